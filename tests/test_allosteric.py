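"""Generalized MWC layer: activity ratio, flux split, L0, Q and Psi."""

import numpy as np
import pytest

import enzkin as ek
from enzkin.allosteric import RegulatorySample
from enzkin.rate_law import ConcentrationState, steady_state


@pytest.fixture(scope="module")
def pepc():
    return ek.make_fixture("pepc")


@pytest.fixture(scope="module")
def pepc_samples(pepc):
    mech, config = pepc
    thermo = ek.ThermoReference(delta_gr=-43.2, v_ref=1.0)
    return ek.sample_ensemble(mech, thermo, 100, seed=21, allosteric_config=config)


def test_activity_ratio_uniform_and_overrides(rng):
    draws = np.array([ek.sample_activity_ratio(rng) for _ in range(20000)])
    assert np.all((draws >= 0) & (draws <= 1))
    assert draws.mean() == pytest.approx(0.5, abs=4 * np.sqrt(1 / 12 / draws.size))
    assert ek.sample_activity_ratio(rng, override=0.0) == 0.0
    assert ek.sample_activity_ratio(rng, override=1.0) == 1.0


def test_split_reference_fluxes_examples():
    assert ek.split_reference_fluxes(1.0, 1, 1.0, 0.3) == (1.0, 0.3)
    v_r, v_t = ek.split_reference_fluxes(1.0, 4, 0.5, 0.2)
    assert (v_r, v_t) == (0.5, pytest.approx(0.1))
    with pytest.raises(ValueError):
        ek.split_reference_fluxes(1.0, 4, 0.0, 0.2)


def test_reassembled_reference_flux(pepc_samples):
    """v = n * v_R * Psi at the reference returns v_ref for every sample."""
    for s in pepc_samples:
        assert s.velocity() == pytest.approx(1.0, abs=1e-8)


def test_compute_L0_examples():
    assert ek.compute_L0(0.2, 0.1, 0.2, 0.1, 4) == pytest.approx(1.0)
    assert ek.compute_L0(0.1, 0.2, 0.4, 0.2, 2) == pytest.approx(4.0)
    with pytest.raises(ValueError):
        ek.compute_L0(0.0, 0.1, 0.2, 0.1, 2)


def test_effector_constants_examples():
    assert ek.effector_constants(0.1, 0.1) == pytest.approx(1.0)
    assert ek.effector_constants(0.2, 0.1) == pytest.approx(2.0)
    with pytest.raises(ValueError):
        ek.effector_constants(0.0, 0.1)


def test_q_limits(pepc, pepc_samples):
    mech, config = pepc
    s = pepc_samples[0]
    reg = s.regulatory
    # L0 = 0: pure R enzyme, Q = 0, Psi = 1
    dead = RegulatorySample(
        config=reg.config, a_ref=reg.a_ref, L0=0.0, K_R=reg.K_R, K_T=reg.K_T,
        v_R_ref=reg.v_R_ref, v_T_ref=reg.v_T_ref, k_R=reg.k_R, k_T=reg.k_T,
    )
    assert ek.evaluate_Q(mech, config, dead) == 0.0
    assert ek.evaluate_psi(mech, dead) == pytest.approx(1.0)
    # saturating activator drives Q -> 0 and Psi -> 1
    st = ConcentrationState(effectors={"fbp": 1e6})
    assert ek.evaluate_Q(mech, config, reg, st) < 1e-6 * reg.Q_ref
    assert ek.evaluate_psi(mech, reg, st) == pytest.approx(1.0, abs=1e-4)


def test_q_constant_without_effectors_for_identical_states(uni_uni):
    """n = 1, no effectors, k_R = k_T: the free-fraction ratio cancels and
    Q = L0 at every concentration state."""
    thermo = ek.ThermoReference(delta_gr=-10.0, v_ref=1.0)
    base = ek.sample_parameter_set(uni_uni, thermo, seed=41)
    config = ek.AllostericConfig(n=1)
    reg = RegulatorySample(
        config=config, a_ref=0.5, L0=7.5, k_R=base.k_scaled, k_T=base.k_scaled
    )
    rng = np.random.default_rng(6)
    for _ in range(10):
        st = ConcentrationState(x={"a": 10 ** rng.uniform(-2, 2), "p": 10 ** rng.uniform(-2, 2)})
        assert ek.evaluate_Q(uni_uni, config, reg, st) == pytest.approx(7.5, rel=1e-12)


def test_non_allosteric_reduction(uni_uni):
    """n = 1, L0 = 0: the oligomer evaluator equals the bare rate law."""
    thermo = ek.ThermoReference(delta_gr=-10.0, v_ref=1.0)
    base = ek.sample_parameter_set(uni_uni, thermo, seed=42)
    reg = RegulatorySample(
        config=ek.AllostericConfig(n=1), a_ref=0.5, L0=0.0,
        k_R=base.k_scaled, k_T=base.k_scaled,
    )
    wrapped = ek.KineticSample(
        mechanism=uni_uni, thermo=thermo, e_ref=base.e_ref,
        reversibilities=base.reversibilities, r_elem=base.r_elem,
        k_scaled=base.k_scaled, regulatory=reg,
    )
    rng = np.random.default_rng(7)
    for _ in range(20):
        st = ConcentrationState(x={"a": 10 ** rng.uniform(-2, 2), "p": 10 ** rng.uniform(-2, 2)})
        assert wrapped.velocity(st) == pytest.approx(base.velocity(st), rel=1e-12)


def test_psi_bounds(pepc, pepc_samples):
    """Psi lies in [min(1, vT/vR), max(1, vT/vR)] pointwise (the structural
    bound of the MWC interpolation) and is at most 1 at the reference."""
    mech, _ = pepc
    rng = np.random.default_rng(8)
    for s in pepc_samples[:30]:
        reg = s.regulatory
        assert 0.0 < reg.psi_ref <= 1.0
        for _ in range(10):
            st = ConcentrationState(
                x={m: 10 ** rng.uniform(-1, 1) for m in mech.metabolites},
                effectors={e: 10 ** rng.uniform(-1, 1) for e in ("fbp", "accoa", "asp", "mal")},
            )
            psi = ek.evaluate_psi(mech, reg, st)
            v_r = steady_state(mech, reg.k_R, st).velocity
            v_t = steady_state(mech, reg.k_T, st).velocity
            if v_r > 0:
                ratio = v_t / v_r
                lo, hi = min(1.0, ratio), max(1.0, ratio)
                assert lo - 1e-9 <= psi <= hi + 1e-9


def test_monotone_activation(pepc, pepc_samples):
    """Raising an R-binding activator never decreases Psi."""
    mech, _ = pepc
    for s in pepc_samples[:20]:
        reg = s.regulatory
        levels = [0.0, 0.1, 1.0, 10.0, 100.0]
        psis = [
            ek.evaluate_psi(mech, reg, ConcentrationState(effectors={"fbp": f}))
            for f in levels
        ]
        assert np.all(np.diff(psis) >= -1e-12)


def test_dead_tense_state(pepc):
    """a_ref = 0 (induced-fit special case): T contributes no flux, and a
    saturating inhibitor with Q -> inf kills the velocity."""
    mech, config = pepc
    cfg0 = ek.AllostericConfig(n=config.n, sites=config.sites, a_ref_override=0.0)
    thermo = ek.ThermoReference(delta_gr=-43.2, v_ref=1.0)
    s = ek.sample_ensemble(mech, thermo, 5, seed=43, allosteric_config=cfg0)[0]
    assert s.regulatory.a_ref == 0.0
    assert s.regulatory.v_T_ref == 0.0
    assert s.velocity() == pytest.approx(1.0, abs=1e-8)
    v_inhibited = s.velocity(ConcentrationState(effectors={"asp": 1e9}))
    assert abs(v_inhibited) < 1e-3 * abs(s.velocity())


def test_config_validation():
    with pytest.raises(ValueError):
        ek.AllostericConfig(n=0)
    eff = ek.Effector("x", "activator")
    with pytest.raises(ValueError):
        ek.AllostericConfig(
            n=2,
            sites=(
                ek.AllostericSite("s1", (eff,)),
                ek.AllostericSite("s2", (eff,)),
            ),
        )
    with pytest.raises(ValueError):
        ek.Effector("y", "catalyst")
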