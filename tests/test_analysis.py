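"""Elasticities, Cleland constants, energetic split, Hill curves, filtering."""

import numpy as np
import pandas as pd
import pytest

import enzkin as ek
from enzkin.analysis import hill_curve
from enzkin.mechanism import MechanismError
from enzkin.rate_law import ConcentrationState


# ---------------------------------------------------------------------------
# elasticities


def test_elasticity_log_linear_rate(uni_uni, thermo10):
    """A binding-limited irreversible step gives a substrate elasticity of 1."""
    # make binding of A rate limiting and everything else fast/irreversible
    k = np.array([1.0, 1e-9, 1e4, 1e-9, 1e4, 1e-9])
    s = ek.KineticSample(
        uni_uni, ek.ThermoReference(delta_gr=-80.0, v_ref=1.0),
        np.full(3, 1 / 3), np.full(3, 0.5), np.ones(3), k,
    )
    v1 = s.velocity(ConcentrationState(x={"a": 1.0, "p": 0.0}))
    eps = (
        (s.velocity(ConcentrationState(x={"a": 1.01, "p": 0.0}))
         - s.velocity(ConcentrationState(x={"a": 0.99, "p": 0.0})))
        / 0.02 / v1
    )
    assert eps == pytest.approx(1.0, abs=1e-3)


def test_elasticity_matches_mm_closed_form(uni_uni):
    """Irreversible Uni-Uni: eps_A = K/(K + 1) at the reference point."""
    rng = np.random.default_rng(51)
    th = ek.ThermoReference(delta_gr=-80.0, v_ref=1.0)
    for _ in range(10):
        k1, k2, k3 = 10 ** rng.uniform(-1, 1, size=3)
        k = np.array([k1, 1e-12, k2, 1e-12, k3, 1e-12])
        km = (k2 * k3) / (k1 * (k2 + k3))  # Michaelis constant, reverse rates ~ 0
        s = ek.KineticSample(uni_uni, th, np.full(3, 1 / 3), np.full(3, 0.5), np.ones(3), k)
        v_ref = s.velocity()
        s = ek.KineticSample(
            uni_uni, ek.ThermoReference(delta_gr=-80.0, v_ref=v_ref),
            np.full(3, 1 / 3), np.full(3, 0.5), np.ones(3), k,
        )
        eps = ek.elasticity(s, "a").value
        assert eps == pytest.approx(km / (km + 1.0), abs=5e-4)


# ---------------------------------------------------------------------------
# Cleland constants and the energetic decomposition


def test_uni_uni_cleland_closed_forms(uni_uni_ensemble):
    """Contracted-limit constants equal the textbook King-Altman expressions."""
    for s in uni_uni_ensemble[:50]:
        k1, km1, k2, km2, k3, km3 = s.k_scaled
        c = ek.cleland_constants(s.mechanism, s.k_scaled)
        assert c.kcat_fwd == pytest.approx(k2 * k3 / (k2 + km2 + k3), rel=1e-10)
        assert c.kcat_rev == pytest.approx(km1 * km2 / (km1 + k2 + km2), rel=1e-10)
        n = km1 * km2 + km1 * k3 + k2 * k3
        assert c.km["a"] == pytest.approx(n / (k1 * (k2 + km2 + k3)), rel=1e-9)
        assert c.km["p"] == pytest.approx(n / (km3 * (km1 + k2 + km2)), rel=1e-9)


def test_haldane_identities_exact(thermo10):
    """The reference-state Haldane relation holds to machine precision with
    the classic constant combination of each compulsory-order mechanism."""
    combos = {
        "ordered_uni_uni": (1, {"a": "m", "p": "m"}),
        "ordered_bi_bi": (1, {"a": "d", "b": "m", "p": "m", "q": "d"}),
        "ordered_ter_ter": (1, {"a": "d", "b": "d", "c": "m", "p": "m", "q": "d", "r": "d"}),
        "ping_pong_bi_bi": (2, {"a": "m", "b": "m", "p": "m", "q": "m"}),
    }
    for name, (cat_power, kinds) in combos.items():
        mech, _ = ek.make_fixture(name)
        s = ek.sample_parameter_set(mech, thermo10, seed=61)
        c = ek.cleland_constants(mech, s.k_scaled)
        total = cat_power * np.log(c.kcat_rev / c.kcat_fwd)
        for m in mech.substrates:
            total += np.log(c.km[m] if kinds[m] == "m" else c.kdiss[m])
        for m in mech.products:
            total -= np.log(c.km[m] if kinds[m] == "m" else c.kdiss[m])
        assert total == pytest.approx(thermo10.dgr_rt, rel=1e-10)


def test_cleland_km_matches_numeric_titration(bi_bi, thermo10):
    """K_A is the half-saturating concentration under saturating co-substrate
    and zero product (direct simulation oracle)."""
    s = ek.sample_parameter_set(bi_bi, thermo10, seed=62)
    c = ek.cleland_constants(bi_bi, s.k_scaled)
    big = 1e9
    state_half = ConcentrationState(x={"a": c.km["a"], "b": big, "p": 0.0, "q": 0.0})
    v_half = s.velocity(state_half)
    assert v_half == pytest.approx(c.kcat_fwd / 2, rel=1e-5)
    state_half_b = ConcentrationState(x={"a": big, "b": c.km["b"], "p": 0.0, "q": 0.0})
    assert s.velocity(state_half_b) == pytest.approx(c.kcat_fwd / 2, rel=1e-5)


def test_random_order_unsupported_for_cleland(uni_bi, thermo10):
    s = ek.sample_parameter_set(uni_bi, thermo10, seed=63)
    with pytest.raises(MechanismError):
        ek.cleland_constants(uni_bi, s.k_scaled)


def test_decomposition_exact_sum(bi_bi_ensemble, thermo10):
    for s in bi_bi_ensemble:
        d = ek.energetic_decomposition(s)
        assert d.catalytic_term + d.binding_term == pytest.approx(
            thermo10.dgr_rt, rel=1e-10
        )
        assert d.catalytic_fraction + d.binding_fraction == pytest.approx(1.0, rel=1e-10)


def test_decomposition_symmetric_catalytic_zero(uni_uni):
    """kcat_fwd = kcat_rev forces a vanishing catalytic term."""
    th = ek.ThermoReference(delta_gr=-10.0, v_ref=1.0)
    # symmetric central step and mirrored outer steps
    k = np.array([2.0, 0.5, 1.0, 1.0, 0.5, 2.0])
    c = ek.cleland_constants(ek.make_fixture("ordered_uni_uni")[0], k)
    assert np.log(c.kcat_rev / c.kcat_fwd) == pytest.approx(0.0, abs=1e-12)


# ---------------------------------------------------------------------------
# Hill curves


class _StubMech:
    products = ()


class _HillStub:
    """Closed-form Hill kinetics v = S^h / (1 + S^h), used to calibrate the
    logit-slope estimator."""

    mechanism = _StubMech()

    def __init__(self, h):
        self.h = h

    def velocity(self, state):
        s = state.conc("s")
        return s**self.h / (1.0 + s**self.h)


@pytest.mark.parametrize("h", [0.5, 1.0, 2.0, 4.0])
def test_hill_estimator_recovers_exponent(h):
    curve = hill_curve(_HillStub(h), "s")
    assert curve.nh_max == pytest.approx(h, abs=0.01)
    if h == 1.0:
        finite = curve.nh[np.isfinite(curve.nh)]
        np.testing.assert_allclose(finite, 1.0, atol=0.01)
        assert curve.classification == "none"
    elif h > 1:
        assert curve.classification == "positive"
    else:
        assert curve.classification == "negative"


def test_hill_curve_on_sampled_glucokinase(glucokinase):
    thermo = ek.glucokinase_protocol()
    s = ek.sample_parameter_set(glucokinase, thermo, seed=71)
    curve = hill_curve(s, "glc")
    assert np.isfinite(curve.nh_max)
    assert curve.classification in ("positive", "negative", "none")
    assert ek.classify_cooperativity(curve) == curve.classification
    ratio = ek.transition_rate_ratio(s)
    assert ratio > 0


def test_transition_ratio_requires_conformational_step(uni_uni, thermo10):
    s = ek.sample_parameter_set(uni_uni, thermo10, seed=72)
    with pytest.raises(MechanismError):
        ek.transition_rate_ratio(s)


# ---------------------------------------------------------------------------
# rejection filter and summaries


def test_rejection_filter_self_consistency(uni_uni, thermo10, rng):
    truth = ek.sample_parameter_set(uni_uni, thermo10, seed=81)
    grid = np.logspace(-1, 1, 12)
    noise = 0.05 * abs(thermo10.v_ref)
    curve = ek.synth_reference_curve(truth, "a", grid, noise, rng)
    others = ek.sample_ensemble(uni_uni, thermo10, 50, seed=82)
    accepted, rate = ek.rejection_filter(
        [truth] + others, curve, "a", tolerance=2 * noise
    )
    assert truth in accepted
    assert 0 < rate <= 1
    # exact curve round-trips at (near-)zero tolerance
    exact = ek.synth_reference_curve(truth, "a", grid, 0.0, rng)
    only_truth, _ = ek.rejection_filter([truth] + others, exact, "a", tolerance=1e-12)
    assert truth in only_truth
    # infinite tolerance accepts everything
    all_acc, rate_inf = ek.rejection_filter([truth] + others, curve, "a", np.inf)
    assert rate_inf == 1.0
    # acceptance is monotone in the tolerance
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rates = [
            ek.rejection_filter([truth] + others, curve, "a", tol)[1]
            for tol in (0.01, 0.05, 0.2, 1.0, np.inf)
        ]
    assert all(r2 >= r1 for r1, r2 in zip(rates, rates[1:]))


def test_rejection_filter_warns_on_empty(uni_uni, thermo10, rng):
    truth = ek.sample_parameter_set(uni_uni, thermo10, seed=83)
    curve = ek.synth_reference_curve(truth, "a", np.logspace(-1, 1, 5), 0.0, rng)
    curve["velocity"] += 100.0  # unreachable reference data
    with pytest.warns(UserWarning):
        accepted, rate = ek.rejection_filter([truth], curve, "a", tolerance=1e-6)
    assert accepted == [] and rate == 0.0


def test_ensemble_summary_order_statistics(rng):
    const = ek.ensemble_summary({"c": [2.0] * 10})
    row = const.iloc[0]
    assert row["median"] == row["lo"] == row["hi"] == 2.0
    u = rng.uniform(0, 1, size=100_000)
    s = ek.ensemble_summary({"u": u}).iloc[0]
    assert s["median"] == pytest.approx(0.5, abs=0.01)
    assert s["lo"] == pytest.approx(0.025, abs=0.005)
    assert s["hi"] == pytest.approx(0.975, abs=0.005)
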