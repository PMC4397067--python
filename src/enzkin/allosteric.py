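"""Generalized Monod–Wyman–Changeux layer for oligomeric enzymes.

The oligomer velocity factorizes as v = Phi_catalytic * Psi_regulatory
with Phi = n * v_R (n identical protomers in the relaxed R conformation)
and Psi = (1 + (v_T/v_R) Q) / (1 + Q), where Q tracks the current T/R
conformational ratio.  Both conformations share the catalytic mechanism
topology but carry independent rate-constant sets; the tense T state is
at most as active as R (activity ratio a_ref = v_T/v_R at reference is
in [0, 1]).

Q combines the allosteric constant L0 (T/R ratio of the unliganded
enzyme), the free-enzyme fractions of both conformations at the current
concentrations, and one saturable factor per allosteric site:

    Q = L0 * ( e_R0(x, k_R) / e_T0(x, k_T)
               * prod_sites (1 + sum_inhibitors  x_F / K_T)
               / prod_sites (1 + sum_activators  x_F / K_R) ) ** n

Activators bind the R state and inhibitors the T state by default
(relaxable per effector).  All dissociation constants are scaled to the
reference effector concentrations, which therefore never need to be
known in absolute terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .mechanism import BINDING, Mechanism, MechanismError, ThermoReference
from .rate_law import REFERENCE_STATE, ConcentrationState, steady_state

__all__ = [
    "Effector",
    "AllostericSite",
    "AllostericConfig",
    "RegulatorySample",
    "sample_activity_ratio",
    "split_reference_fluxes",
    "compute_L0",
    "effector_constants",
    "evaluate_Q",
    "evaluate_psi",
    "evaluate_velocity",
    "sample_regulatory",
]

#: pseudo reference flux (relative to v_R) used to parameterize a
#: catalytically dead T conformation (a_ref = 0) so its intermediate
#: fractions remain well defined
DEAD_STATE_FLUX = 1e-12


@dataclass(frozen=True)
class Effector:
    """An allosteric effector: activators bind R, inhibitors bind T."""

    name: str
    role: str  # "activator" | "inhibitor"
    binds_both: bool = False  # relax the exclusive-binding constraint

    def __post_init__(self) -> None:
        if self.role not in ("activator", "inhibitor"):
            raise ValueError(f"unknown effector role {self.role!r}")


@dataclass(frozen=True)
class AllostericSite:
    id: str
    effectors: tuple[Effector, ...]


@dataclass(frozen=True)
class AllostericConfig:
    """Conformational structure of an oligomer: n subunits, m allosteric sites."""

    n: int
    sites: tuple[AllostericSite, ...] = ()
    symmetric_binding: bool = True
    a_ref_override: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("subunit count n must be >= 1")
        seen: set[str] = set()
        for site in self.sites:
            for eff in site.effectors:
                if eff.name in seen:
                    raise ValueError(f"effector {eff.name!r} assigned to two sites")
                seen.add(eff.name)
        if self.a_ref_override is not None and not 0.0 <= self.a_ref_override <= 1.0:
            raise ValueError("a_ref override must lie in [0, 1]")

    @property
    def m(self) -> int:
        return len(self.sites)


@dataclass(eq=False)
class RegulatorySample:
    """Sampled regulatory layer tied to one kinetic parameter set.

    ``k_R``/``k_T`` are the scaled rate-constant vectors of the two
    conformations, assembled against their own reference fluxes
    v_R_ref and v_T_ref = a_ref * v_R_ref.
    """

    config: AllostericConfig
    a_ref: float
    L0: float
    K_R: dict[tuple[str, str], float] = field(default_factory=dict)
    K_T: dict[tuple[str, str], float] = field(default_factory=dict)
    v_R_ref: float = 0.0
    v_T_ref: float = 0.0
    k_R: np.ndarray | None = None
    k_T: np.ndarray | None = None
    e_R: np.ndarray | None = None
    e_T: np.ndarray | None = None
    Q_ref: float = 0.0
    psi_ref: float = 1.0


def sample_activity_ratio(
    rng: np.random.Generator, override: Optional[float] = None
) -> float:
    """Activity ratio a_ref = v_T_ref / v_R_ref ~ Uniform(0, 1).

    An explicit override (e.g. 0 for a catalytically dead T state) is
    honoured verbatim.
    """
    if override is not None:
        if not 0.0 <= override <= 1.0:
            raise ValueError("a_ref override must lie in [0, 1]")
        return float(override)
    return float(rng.uniform(0.0, 1.0))


def split_reference_fluxes(
    v_ref: float, n: int, psi_ref: float, a_ref: float
) -> tuple[float, float]:
    """Partition the oligomer reference flux into protomer fluxes.

    v_R_ref = v_ref / (n * Psi_ref) and v_T_ref = a_ref * v_R_ref.
    """
    if psi_ref <= 0.0:
        raise ValueError("psi_ref must be positive")
    if n < 1:
        raise ValueError("n must be >= 1")
    v_r = v_ref / (n * psi_ref)
    return v_r, a_ref * v_r


def compute_L0(
    e_R0: float, e_R1: float, e_T0: float, e_T1: float, n: int
) -> float:
    """Allosteric constant from reference free/ligand-bound fractions.

    L0 = ((e_T0/e_T1) / (e_R0/e_R1)) ** (n/2) under symmetric binding of
    the n subunits.
    """
    for v in (e_R0, e_R1, e_T0, e_T1):
        if v <= 0.0:
            raise ValueError("free and bound fractions must be strictly positive")
    return float(((e_T0 / e_T1) / (e_R0 / e_R1)) ** (n / 2.0))


def effector_constants(
    e0: float, e1: float, reference_effector_conc: float = 1.0
) -> float:
    """Scaled effector dissociation constant K = (e0/e1) * x_F_ref.

    ``e0``/``e1`` are the effector-free and effector-bound enzyme
    fractions of one conformational state at the reference point.
    Absolute effector concentrations are pure scaling factors and never
    required.
    """
    if e0 <= 0.0 or e1 <= 0.0:
        raise ValueError("fractions must be strictly positive")
    return float(e0 / e1 * reference_effector_conc)


def _site_factors(
    config: AllostericConfig,
    K_R: dict[tuple[str, str], float],
    K_T: dict[tuple[str, str], float],
    state: ConcentrationState,
) -> tuple[float, float]:
    """(numerator, denominator) site products of Q at the given state."""
    num = 1.0  # T-binding (inhibitor) factors
    den = 1.0  # R-binding (activator) factors
    for site in config.sites:
        t_sum = 0.0
        r_sum = 0.0
        for eff in site.effectors:
            xf = state.effector(eff.name)
            key = (site.id, eff.name)
            if key in K_T:
                t_sum += xf / K_T[key]
            if key in K_R:
                r_sum += xf / K_R[key]
        num *= 1.0 + t_sum
        den *= 1.0 + r_sum
    return num, den


def evaluate_Q(
    mech: Mechanism,
    config: AllostericConfig,
    reg: RegulatorySample,
    state: ConcentrationState = REFERENCE_STATE,
) -> float:
    """Conformational ratio function Q >= 0 at a concentration state."""
    if reg.L0 == 0.0:
        return 0.0
    e_r0 = steady_state(mech, reg.k_R, state).free_enzyme_fraction
    e_t0 = steady_state(mech, reg.k_T, state).free_enzyme_fraction
    num, den = _site_factors(config, reg.K_R, reg.K_T, state)
    if e_t0 <= 0.0:
        return np.inf
    return float(reg.L0 * (e_r0 / e_t0 * num / den) ** config.n)


def evaluate_psi(
    mech: Mechanism,
    reg: RegulatorySample,
    state: ConcentrationState = REFERENCE_STATE,
) -> float:
    """Regulatory function Psi = (1 + (v_T/v_R) Q) / (1 + Q) at a state."""
    q = evaluate_Q(mech, reg.config, reg, state)
    v_r = steady_state(mech, reg.k_R, state).velocity
    v_t = 0.0 if reg.a_ref == 0.0 else steady_state(mech, reg.k_T, state).velocity
    if np.isinf(q):
        return v_t / v_r if v_r != 0.0 else 0.0
    if v_r == 0.0:
        return 1.0
    return (v_r + v_t * q) / (v_r * (1.0 + q))


def evaluate_velocity(sample, state: ConcentrationState = REFERENCE_STATE) -> float:
    """Oligomer velocity v = n * v_R(x) * Psi(x) = n (v_R + v_T Q)/(1 + Q)."""
    reg = sample.regulatory
    mech = sample.mechanism
    q = evaluate_Q(mech, reg.config, reg, state)
    v_r = steady_state(mech, reg.k_R, state).velocity
    v_t = 0.0 if reg.a_ref == 0.0 else steady_state(mech, reg.k_T, state).velocity
    if np.isinf(q):
        return reg.config.n * v_t
    return reg.config.n * (v_r + v_t * q) / (1.0 + q)


def _first_bound_intermediate(mech: Mechanism) -> str:
    """Product of the first substrate-binding step out of the free enzyme.

    Its abundance plays the role of the ligand-bound fraction e_1 in the
    allosteric-constant estimate.
    """
    for st in mech.steps:
        if st.role == BINDING and st.reactant == mech.free_enzyme:
            return st.product
    raise MechanismError(
        f"mechanism {mech.name!r} has no substrate-binding step from the free enzyme"
    )


def sample_regulatory(
    mech: Mechanism,
    thermo: ThermoReference,
    config: AllostericConfig,
    constraints,
    rng: np.random.Generator,
    seed_info: tuple[int, int] = (0, 0),
):
    """Sample a full allosteric parameter set (protomer kinetics x2 + MWC layer).

    Order of operations (each quantity available when needed): abundances
    for R and T; allosteric constant and effector dissociation constants
    from those abundances; Q_ref, a_ref and hence Psi_ref; reference-flux
    split; reversibilities/branching and rate-constant assembly per
    conformation against its own reference flux.
    """
    from .sampler import (
        KineticSample,
        assemble_rate_constants,
        sample_abundances,
        sample_branching,
        sample_reversibilities,
    )

    i_free = mech.intermediate_index(mech.free_enzyme)
    i_bound = mech.intermediate_index(_first_bound_intermediate(mech))

    e_r = sample_abundances(mech.p, rng)
    e_t = sample_abundances(mech.p, rng)
    L0 = compute_L0(e_r[i_free], e_r[i_bound], e_t[i_free], e_t[i_bound], config.n)

    K_R: dict[tuple[str, str], float] = {}
    K_T: dict[tuple[str, str], float] = {}
    for site in config.sites:
        for eff in site.effectors:
            key = (site.id, eff.name)
            if eff.role == "activator" or eff.binds_both:
                f0, f1 = sample_abundances(2, rng)
                K_R[key] = effector_constants(f0, f1)
            if eff.role == "inhibitor" or eff.binds_both:
                f0, f1 = sample_abundances(2, rng)
                K_T[key] = effector_constants(f0, f1)

    a_ref = sample_activity_ratio(rng, config.a_ref_override)

    num, den = _site_factors(config, K_R, K_T, REFERENCE_STATE)
    q_ref = L0 * (e_r[i_free] / e_t[i_free] * num / den) ** config.n
    psi_ref = (1.0 + a_ref * q_ref) / (1.0 + q_ref)
    v_r_ref, v_t_ref = split_reference_fluxes(thermo.v_ref, config.n, psi_ref, a_ref)

    def _protomer_k(e_ref: np.ndarray, v: float) -> np.ndarray:
        rev = sample_reversibilities(constraints, thermo, rng)
        r_elem = sample_branching(mech, v, rng)
        return assemble_rate_constants(mech, e_ref, rev, r_elem, thermo.sgn), rev, r_elem

    k_r, rev_r, r_elem_r = _protomer_k(e_r, v_r_ref)
    v_t_param = v_t_ref if a_ref > 0.0 else DEAD_STATE_FLUX * abs(v_r_ref)
    k_t, _, _ = _protomer_k(e_t, v_t_param)

    reg = RegulatorySample(
        config=config,
        a_ref=a_ref,
        L0=L0,
        K_R=K_R,
        K_T=K_T,
        v_R_ref=v_r_ref,
        v_T_ref=v_t_ref,
        k_R=k_r,
        k_T=k_t,
        e_R=e_r,
        e_T=e_t,
        Q_ref=float(q_ref),
        psi_ref=float(psi_ref),
    )
    return KineticSample(
        mechanism=mech,
        thermo=thermo,
        e_ref=e_r,
        reversibilities=rev_r,
        r_elem=r_elem_r,
        k_scaled=k_r,
        seed_info=seed_info,
        regulatory=reg,
    )
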