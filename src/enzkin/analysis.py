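"""Ensemble analyses: elasticities, energetic decomposition, cooperativity.

The analyses operate on sampled kinetic parameter sets:

* scaled elasticities by central finite differences around the
  reference state;
* macroscopic (Cleland) constants for compulsory-order mechanisms via
  exact saturating-limit contractions of the elementary network, and the
  resulting catalytic/binding split of dGr/RT;
* Hill curves (local logit slope of the saturation curve) and
  cooperativity classification;
* a rejection (ABC-style) filter against reference saturation curves;
* median / 95%-band ensemble summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .mechanism import BINDING, ISOMERIZATION, RELEASE, Mechanism, MechanismError
from .rate_law import ConcentrationState
from .sampler import KineticSample

__all__ = [
    "Elasticity",
    "ClelandConstants",
    "EnergeticDecomposition",
    "HillCurve",
    "elasticity",
    "cleland_constants",
    "energetic_decomposition",
    "hill_curve",
    "classify_cooperativity",
    "transition_rate_ratio",
    "rejection_filter",
    "ensemble_summary",
]

#: relative perturbation for central-difference elasticities
DEFAULT_STEP = 1e-2
#: dead band around nH = 1 for cooperativity classification
COOPERATIVITY_DELTA = 1e-3


# ---------------------------------------------------------------------------
# elasticities


@dataclass(frozen=True)
class Elasticity:
    species: str
    value: float
    step_size: float


def elasticity(
    sample: KineticSample,
    species: str,
    step_size: float = DEFAULT_STEP,
    base_state: Optional[ConcentrationState] = None,
) -> Elasticity:
    """Scaled sensitivity eps = (x/v) dv/dx at the reference neighborhood.

    Central difference with a 1% perturbation by default, normalized by
    the reference concentration (1) and reference flux.
    """
    v_ref = sample.thermo.v_ref
    if v_ref == 0.0:
        raise ValueError("reference flux is zero; elasticity undefined")
    base = base_state.x if base_state is not None else {}
    eff = base_state.effectors if base_state is not None else {}
    up = dict(base)
    dn = dict(base)
    x0 = float(base.get(species, 1.0))
    up[species] = x0 + step_size
    dn[species] = x0 - step_size
    v_up = sample.velocity(ConcentrationState(x=up, effectors=eff))
    v_dn = sample.velocity(ConcentrationState(x=dn, effectors=eff))
    val = (v_up - v_dn) / (2.0 * step_size) * x0 / v_ref
    return Elasticity(species=species, value=float(val), step_size=step_size)


# ---------------------------------------------------------------------------
# Cleland macroscopic constants via saturating-limit contraction


@lru_cache(maxsize=None)
def _require_compulsory(mech: Mechanism) -> None:
    from .mechanism import build_cycle_constraints

    cc = build_cycle_constraints(mech)
    if not cc.is_compulsory_order:
        raise MechanismError(
            f"macroscopic constants are defined here only for compulsory-order "
            f"mechanisms; {mech.name!r} is random-order"
        )


@lru_cache(maxsize=None)
def _contraction(mech: Mechanism, saturated: frozenset) -> tuple:
    """Merge the endpoints of every step binding/releasing a saturated
    metabolite (its second-order direction becomes infinitely fast) and
    return the reduced topology.

    In the saturating limit the merged pool concentrates entirely in the
    metabolite-bound member, so the unbound member's share vanishes and
    every rate draining it through a non-contracted step drops out of the
    limit.  Returns (node_of_intermediate, n_nodes, kept_step_indices,
    vanished_intermediate_indices).
    """
    parent = list(range(mech.p))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    kept = []
    vanished: set[int] = set()
    for j, st in enumerate(mech.steps):
        if st.metabolite is not None and st.metabolite in saturated:
            u = mech.intermediate_index(st.reactant)
            w = mech.intermediate_index(st.product)
            parent[max(find(u), find(w))] = min(find(u), find(w))
            # binding step: the free (reactant) form empties; release
            # step: saturated rebinding empties the released (product) form
            vanished.add(u if st.role == BINDING else w)
        else:
            kept.append(j)
    roots = sorted({find(i) for i in range(mech.p)})
    node_of = tuple(roots.index(find(i)) for i in range(mech.p))
    return node_of, len(roots), tuple(kept), tuple(sorted(vanished))


def _contracted_velocity(
    mech: Mechanism,
    k: np.ndarray,
    saturated: frozenset,
    x: Mapping[str, float],
    measured: str,
) -> float:
    """Steady-state net production rate of ``measured`` per total enzyme in
    the network with the ``saturated`` metabolites' steps contracted."""
    node_of, n, kept, vanished = _contraction(mech, saturated)
    a = np.zeros((n, n))
    flux_terms = []  # (sign, coeff, from-node) pairs for the measured cut
    for j in kept:
        st = mech.steps[j]
        iu, iw = mech.intermediate_index(st.reactant), mech.intermediate_index(st.product)
        u, w = node_of[iu], node_of[iw]
        a_fwd, a_rev = k[2 * j], k[2 * j + 1]
        if st.role == BINDING:
            a_fwd *= x.get(st.metabolite, 1.0)
        elif st.role == RELEASE:
            a_rev *= x.get(st.metabolite, 1.0)
        if u != w:  # vanished-member rates drop unless internal to a pool
            if iu in vanished:
                a_fwd = 0.0
            if iw in vanished:
                a_rev = 0.0
        a[w, u] += a_fwd
        a[u, u] -= a_fwd
        a[u, w] += a_rev
        a[w, w] -= a_rev
        if st.metabolite == measured:
            sgn = 1.0 if st.role == RELEASE else -1.0
            flux_terms.append((sgn, a_fwd, u, a_rev, w))
    a[0, :] = 1.0
    b = np.zeros(n)
    b[0] = 1.0
    e = np.linalg.solve(a, b)
    return float(sum(s * (af * e[u] - ar * e[w]) for s, af, u, ar, w in flux_terms))


@dataclass(frozen=True)
class ClelandConstants:
    """Macroscopic constants of a compulsory-order mechanism.

    ``kcat_fwd``/``kcat_rev`` are the turnover numbers at saturating
    substrates/products (1/min, scaled units); ``km`` holds Michaelis
    constants per reactant (half-saturation under saturating co-reactants
    and absent counter-reactants); ``kdiss`` the elementary dissociation
    constants of each binding/release step, keyed by metabolite.
    """

    kcat_fwd: float
    kcat_rev: float
    km: dict[str, float]
    kdiss: dict[str, float]


def cleland_constants(mech: Mechanism, k_scaled: np.ndarray) -> ClelandConstants:
    """Exact macroscopic constants from the scaled elementary constants.

    Saturating limits are evaluated by contracting the saturated binding
    steps of the elementary network (the exact limit of the steady-state
    solution), not by large-concentration extrapolation.  Supported for
    compulsory-order (ordered and ping-pong) mechanisms; random-order
    patterns raise :class:`MechanismError`.
    """
    _require_compulsory(mech)
    k = np.asarray(k_scaled, dtype=float)
    subs, prods = mech.substrates, mech.products
    zero_p = {m: 0.0 for m in prods}
    zero_s = {m: 0.0 for m in subs}

    kcat_fwd = _contracted_velocity(
        mech, k, frozenset(subs), zero_p, mech.reference_product
    )
    kcat_rev = _contracted_velocity(mech, k, frozenset(prods), zero_s, subs[0])

    km: dict[str, float] = {}
    for s in subs:
        v1 = _contracted_velocity(
            mech, k, frozenset(set(subs) - {s}), {**zero_p, s: 1.0}, mech.reference_product
        )
        km[s] = (kcat_fwd - v1) / v1
    for pr in prods:
        v1 = _contracted_velocity(
            mech, k, frozenset(set(prods) - {pr}), {**zero_s, pr: 1.0}, subs[0]
        )
        km[pr] = (kcat_rev - v1) / v1

    kdiss: dict[str, float] = {}
    for j, st in enumerate(mech.steps):
        if st.role == BINDING:
            kdiss[st.metabolite] = k[2 * j + 1] / k[2 * j]
        elif st.role == RELEASE:
            kdiss[st.metabolite] = k[2 * j] / k[2 * j + 1]
    return ClelandConstants(
        kcat_fwd=float(kcat_fwd), kcat_rev=float(kcat_rev), km=km, kdiss=kdiss
    )


@dataclass(frozen=True)
class EnergeticDecomposition:
    """Split of dGr/RT into catalytic (turnover) and binding (saturation)
    terms; the two sum to dGr/RT exactly and the fractions to one."""

    catalytic_term: float
    binding_term: float
    catalytic_fraction: float
    binding_fraction: float


def energetic_decomposition(sample: KineticSample) -> EnergeticDecomposition:
    """Catalytic/binding energetic split of one sampled parameter set.

    The catalytic term is ln(kcat_rev/kcat_fwd) with the Cleland turnover
    numbers; the binding term is the paired sum of log dissociation
    constants, which by the reference-state Haldane relation equals
    dGr/RT minus the catalytic term (enforced exactly).
    """
    consts = cleland_constants(sample.mechanism, sample.k_scaled)
    dgr_rt = sample.thermo.dgr_rt
    catalytic = float(np.log(consts.kcat_rev / consts.kcat_fwd))
    binding = dgr_rt - catalytic
    return EnergeticDecomposition(
        catalytic_term=catalytic,
        binding_term=binding,
        catalytic_fraction=catalytic / dgr_rt,
        binding_fraction=binding / dgr_rt,
    )


# ---------------------------------------------------------------------------
# Hill curves and cooperativity


@dataclass(frozen=True)
class HillCurve:
    substrate: str
    grid: np.ndarray
    velocities: np.ndarray
    nh: np.ndarray
    nh_max: float
    nh_min: float
    v_sat: float
    saturating: bool
    classification: str


def _initial_velocity_state(
    mech: Mechanism, substrate: str, conc: float, base: Optional[ConcentrationState]
) -> ConcentrationState:
    x = dict(base.x) if base is not None else {}
    for pr in mech.products:
        x.setdefault(pr, 0.0)
    x[substrate] = conc
    return ConcentrationState(x=x, effectors=base.effectors if base is not None else {})


def hill_curve(
    sample: KineticSample,
    substrate: str,
    grid: Optional[np.ndarray] = None,
    base_state: Optional[ConcentrationState] = None,
) -> HillCurve:
    """Local Hill coefficient nH(S) = d ln(v/(V_sat - v)) / d ln S.

    Initial-velocity convention: products at 0, co-substrates at their
    reference values unless overridden.  The saturating velocity is
    taken from a far point (1e4 x the top of the grid) so the logit is
    well defined across the grid; a curve whose interior maximum exceeds
    that asymptote (apparent substrate inhibition) is flagged
    non-saturating and its logit masked where undefined.
    """
    mech = sample.mechanism
    if grid is None:
        grid = np.logspace(-2.0, 2.0, 60)
    grid = np.asarray(grid, dtype=float)
    v = np.array(
        [
            sample.velocity(_initial_velocity_state(mech, substrate, g, base_state))
            for g in grid
        ]
    )
    v_far = sample.velocity(
        _initial_velocity_state(mech, substrate, grid[-1] * 1e4, base_state)
    )
    saturating = bool(v.max() <= v_far * (1.0 + 1e-6))
    v_sat = max(float(v_far), float(v.max())) * (1.0 + 1e-9)
    with np.errstate(divide="ignore", invalid="ignore"):
        y = np.where((v > 0) & (v < v_sat), np.log(v / (v_sat - v)), np.nan)
    lng = np.log(grid)
    nh = np.full(len(grid), np.nan)
    nh[1:-1] = (y[2:] - y[:-2]) / (lng[2:] - lng[:-2])
    finite = nh[np.isfinite(nh)]
    nh_max = float(finite.max()) if finite.size else np.nan
    nh_min = float(finite.min()) if finite.size else np.nan
    if np.isfinite(nh_max) and nh_max > 1.0 + COOPERATIVITY_DELTA:
        cls = "positive"
    elif np.isfinite(nh_min) and nh_min < 1.0 - COOPERATIVITY_DELTA:
        cls = "negative"
    else:
        cls = "none"
    return HillCurve(
        substrate=substrate,
        grid=grid,
        velocities=v,
        nh=nh,
        nh_max=nh_max,
        nh_min=nh_min,
        v_sat=v_sat,
        saturating=saturating,
        classification=cls,
    )


def classify_cooperativity(curve: HillCurve) -> str:
    """positive (nH_max > 1), negative (dips below 1 without exceeding it),
    or none."""
    return curve.classification


def transition_rate_ratio(sample: KineticSample) -> float:
    """Forward/reverse rate-constant ratio of the conformational step
    from the low- to the high-affinity free-enzyme state.

    For mnemonic mechanisms this is the isomerization step attached to
    the free enzyme; a ratio below 1 marks a slow low-to-high transition,
    the regime that produces kinetic cooperativity.
    """
    mech = sample.mechanism
    for j, st in enumerate(mech.steps):
        if st.role == ISOMERIZATION and mech.free_enzyme in (st.reactant, st.product):
            # declared direction is high -> low affinity (E -> E*); the
            # low -> high forward constant is therefore the reverse one
            if st.reactant == mech.free_enzyme:
                return float(sample.k_scaled[2 * j + 1] / sample.k_scaled[2 * j])
            return float(sample.k_scaled[2 * j] / sample.k_scaled[2 * j + 1])
    raise MechanismError(
        f"mechanism {mech.name!r} has no conformational step at the free enzyme"
    )


# ---------------------------------------------------------------------------
# rejection filter and summaries


def _rms_distance(pred: np.ndarray, obs: np.ndarray) -> float:
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def rejection_filter(
    samples: Sequence[KineticSample],
    reference_curve: pd.DataFrame,
    substrate: str,
    tolerance: float,
    distance: Callable[[np.ndarray, np.ndarray], float] = _rms_distance,
    base_state: Optional[ConcentrationState] = None,
) -> tuple[list[KineticSample], float]:
    """ABC-style rejection step against a reference saturation curve.

    Keeps the samples whose predicted curve lies within ``tolerance`` of
    the observed one under ``distance`` (root-mean-square by default).
    Returns (accepted samples, acceptance rate).
    """
    conc = reference_curve["concentration"].to_numpy(dtype=float)
    obs = reference_curve["velocity"].to_numpy(dtype=float)
    accepted = []
    for s in samples:
        base = base_state if base_state is not None else ConcentrationState()
        pred = []
        for g in conc:
            x = dict(base.x)
            x[substrate] = g
            pred.append(s.velocity(ConcentrationState(x=x, effectors=base.effectors)))
        if distance(np.asarray(pred), obs) <= tolerance:
            accepted.append(s)
    rate = len(accepted) / len(samples) if samples else 0.0
    if samples and not accepted:
        warnings.warn("rejection filter accepted no samples", stacklevel=2)
    return accepted, rate


def ensemble_summary(
    values_per_condition: Mapping[object, Iterable[float]],
    percentiles: tuple[float, float] = (2.5, 97.5),
) -> pd.DataFrame:
    """Median and empirical percentile band per condition."""
    rows = []
    for cond, vals in values_per_condition.items():
        arr = np.asarray(list(vals), dtype=float)
        rows.append(
            {
                "condition": cond,
                "n": arr.size,
                "median": float(np.median(arr)),
                "lo": float(np.percentile(arr, percentiles[0])),
                "hi": float(np.percentile(arr, percentiles[1])),
            }
        )
    return pd.DataFrame(rows)
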