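import numpy as np
import pytest

import enzkin as ek


@pytest.fixture(scope="session")
def uni_uni():
    return ek.make_fixture("ordered_uni_uni")[0]


@pytest.fixture(scope="session")
def bi_bi():
    return ek.make_fixture("ordered_bi_bi")[0]


@pytest.fixture(scope="session")
def uni_bi():
    return ek.make_fixture("random_uni_bi")[0]


@pytest.fixture(scope="session")
def glucokinase():
    return ek.make_fixture("glucokinase_mnemonic")[0]


@pytest.fixture(scope="session")
def thermo10():
    return ek.ThermoReference(delta_gr=-10.0, v_ref=1.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def bi_bi_ensemble(bi_bi, thermo10):
    return ek.sample_ensemble(bi_bi, thermo10, 300, seed=7)


@pytest.fixture(scope="session")
def uni_uni_ensemble(uni_uni, thermo10):
    return ek.sample_ensemble(uni_uni, thermo10, 300, seed=11)
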