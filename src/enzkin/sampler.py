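"""Thermodynamically consistent sampling of kinetic parameter sets.

One parameter set for a protomer is assembled from three independently
sampled ingredients, all anchored at the reference state:

* enzyme-intermediate abundances ``e_ref`` — uniform on the p-simplex;
* step reversibilities ``R_i`` in (0, 1) — the ratio of reverse to
  forward elementary flux, constrained along every fundamental cycle by
  sum(ln R_i) = sgn(v_ref) * dGr / RT (microscopic reversibility carried
  to the non-equilibrium steady state);
* a branching vector ``r_elem`` of non-negative net elementary fluxes in
  the null space of S_pattern, rescaled so its maximum equals |v_ref|.

The scaled rate constants then follow as k = P(e_ref)^-1 * Gamma(R) *
r_elem, which reproduces the reference flux at unit normalized
concentrations by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

import numpy as np
from scipy.optimize import linprog

from .mechanism import (
    CycleConstraints,
    Mechanism,
    MechanismError,
    ThermoReference,
    build_cycle_constraints,
)
from . import rate_law

__all__ = [
    "KineticSample",
    "sample_abundances",
    "sample_reversibilities",
    "sample_branching",
    "gamma_matrix",
    "assemble_rate_constants",
    "accuracy_check",
    "sample_parameter_set",
    "sample_ensemble",
]

logger = logging.getLogger(__name__)

#: default accuracy-check tolerance on |v(ref) - v_ref| [mM/min]
DEFAULT_EPSILON = 1e-8
#: retry cap for infeasible LP lower-bound draws
LP_RETRY_CAP = 100
#: dead branches are nudged to this fraction of |v_ref| to keep all k finite
DEAD_BRANCH_NUDGE = 1e-12


@dataclass(eq=False)
class KineticSample:
    """One sampled, thermodynamically consistent kinetic parameter set."""

    mechanism: Mechanism
    thermo: ThermoReference
    e_ref: np.ndarray
    reversibilities: np.ndarray
    r_elem: np.ndarray
    k_scaled: np.ndarray
    seed_info: tuple[int, int] = (0, 0)
    regulatory: Optional["RegulatorySample"] = None  # noqa: F821  (allosteric module)

    def velocity(self, state=rate_law.REFERENCE_STATE) -> float:
        """Net velocity at a concentration state (oligomer-level if allosteric)."""
        if self.regulatory is not None:
            from .allosteric import evaluate_velocity

            return evaluate_velocity(self, state)
        return rate_law.velocity(self.mechanism, self.k_scaled, state)


def sample_abundances(p: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform draw from the interior of the p-simplex (Dirichlet(1,...,1)).

    Constructed from unit-rate gamma variates normalized by their sum.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    g = rng.standard_gamma(1.0, size=p)
    while np.any(g == 0.0) or g.sum() == 0.0:  # pragma: no cover - measure zero
        g = rng.standard_gamma(1.0, size=p)
    return g / g.sum()


def sample_reversibilities(
    constraints: CycleConstraints,
    thermo: ThermoReference,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw a reversibility vector satisfying every cycle-sum constraint.

    Scaled reversibilities ln(R^hat) live in [0, 1] with
    omega_rev . ln(R^hat) = 1.  Compulsory-order mechanisms reduce to a
    single simplex constraint and are drawn directly from Dirichlet(1).
    Random-order mechanisms draw Dirichlet lower bounds and solve an LP
    maximizing the total scaled reversibility, which lands on varying
    corners of the feasible polytope; infeasible bound draws are
    resampled up to a cap.
    """
    omega = constraints.omega_rev
    q = omega.shape[1]
    if constraints.is_compulsory_order:
        ln_rhat = sample_abundances(q, rng)
    else:
        for _ in range(LP_RETRY_CAP):
            lb = sample_abundances(q, rng)
            res = linprog(
                c=-np.ones(q),
                A_eq=omega,
                b_eq=np.ones(omega.shape[0]),
                bounds=list(zip(lb, np.ones(q))),
                method="highs",
            )
            if res.status == 0:
                ln_rhat = res.x
                break
        else:
            raise RuntimeError(
                f"no feasible reversibility bounds found in {LP_RETRY_CAP} draws"
            )
    ln_r = ln_rhat * thermo.cycle_sum
    return np.exp(ln_r)


@lru_cache(maxsize=None)
def _branching_basis(mech: Mechanism) -> np.ndarray:
    """Non-negative null-space basis of S_pattern from cycle indicators.

    Each fundamental cycle's step-indicator vector lies in the null
    space; for all supported patterns these indicators span it.
    """
    cc = build_cycle_constraints(mech)
    basis = cc.omega_rev.T  # q x n_cycles
    if np.linalg.matrix_rank(basis) < mech.nullity:
        raise MechanismError(
            f"cycle indicators of {mech.name!r} do not span the null space; "
            "branching sampler unsupported for this pattern"
        )
    return basis


def sample_branching(
    mech: Mechanism, v_ref: float, rng: np.random.Generator
) -> np.ndarray:
    """Sample non-negative net elementary fluxes with max equal to |v_ref|.

    Weights on the non-negative cycle basis are drawn uniformly on
    [0, 1]; the combination is rescaled so the largest entry equals
    |v_ref|.  Entries of exactly zero (dead branches) are nudged to a
    tiny positive flux so the rate-constant assembly stays finite.
    """
    basis = _branching_basis(mech)
    for _ in range(LP_RETRY_CAP):
        w = rng.uniform(0.0, 1.0, size=basis.shape[1])
        v_net = basis @ w
        m = v_net.max()
        if m > 0.0:
            break
    else:  # pragma: no cover - probability ~0
        raise RuntimeError("failed to draw a nonzero branching vector")
    r = abs(v_ref) * v_net / m
    r[r == 0.0] = DEAD_BRANCH_NUDGE * abs(v_ref)
    return r


def gamma_matrix(reversibilities: np.ndarray, sgn: int) -> tuple[np.ndarray, np.ndarray]:
    """Diagonal factors converting net fluxes to forward/reverse fluxes.

    Returns ``(gamma_fwd, gamma_rev)`` with gamma_fwd = 1/(1 - R^sgn) and
    gamma_rev = R^sgn/(1 - R^sgn); their difference is 1 for every step,
    so gamma * r_elem splits each net flux into its uni-directional
    components.
    """
    r = np.asarray(reversibilities, dtype=float)
    if np.any(r <= 0.0) or np.any(r >= 1.0):
        raise ValueError("reversibilities must lie strictly in (0, 1)")
    rs = r**sgn
    gamma_fwd = 1.0 / (1.0 - rs)
    gamma_rev = rs / (1.0 - rs)
    return gamma_fwd, gamma_rev


def assemble_rate_constants(
    mech: Mechanism,
    e_ref: np.ndarray,
    reversibilities: np.ndarray,
    r_elem: np.ndarray,
    sgn: int = 1,
) -> np.ndarray:
    """Assemble scaled rate constants k = P^-1(e_ref) Gamma(R) r_elem.

    ``P`` is diagonal with the abundance of the intermediate consumed by
    each uni-directional elementary flux (all normalized concentrations
    are 1 at reference), hence invertible only for strictly positive
    abundances.  Returns the 2q vector interleaved forward/reverse.
    """
    e = np.asarray(e_ref, dtype=float)
    if np.any(e <= 0.0):
        raise ValueError("all intermediate abundances must be strictly positive")
    gamma_fwd, gamma_rev = gamma_matrix(reversibilities, sgn)
    ridx = np.array([mech.intermediate_index(s.reactant) for s in mech.steps])
    pidx = np.array([mech.intermediate_index(s.product) for s in mech.steps])
    v_net = sgn * np.asarray(r_elem, dtype=float)
    k = np.empty(2 * mech.q)
    k[0::2] = gamma_fwd * v_net / e[ridx]
    k[1::2] = gamma_rev * v_net / e[pidx]
    if np.any(k <= 0.0):
        raise ValueError("assembled rate constants are not all positive")
    return k


def accuracy_check(
    sample: KineticSample, tol: float = DEFAULT_EPSILON
) -> bool:
    """Accept a sample iff it reproduces the reference flux within ``tol``."""
    v = sample.velocity()
    return abs(v - sample.thermo.v_ref) < tol


@lru_cache(maxsize=None)
def _cached_constraints(mech: Mechanism) -> CycleConstraints:
    return build_cycle_constraints(mech)


def sample_parameter_set(
    mech: Mechanism,
    thermo: ThermoReference,
    allosteric_config=None,
    rng: Optional[np.random.Generator] = None,
    *,
    seed: Optional[int] = None,
    draw_index: int = 0,
    epsilon: float = DEFAULT_EPSILON,
) -> KineticSample:
    """Draw one accepted kinetic parameter set (orchestrator).

    With an allosteric configuration the regulatory layer (conformational
    split, allosteric constant, effector dissociation constants and the
    two conformations' rate constants) is sampled as well.  The sample is
    re-drawn until the accuracy check passes; rejections are counted on
    ``sample_parameter_set.rejections``.
    """
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence(0 if seed is None else seed).spawn(draw_index + 1)[-1]
        )
    constraints = _cached_constraints(mech)
    for _ in range(LP_RETRY_CAP):
        if allosteric_config is None:
            e_ref = sample_abundances(mech.p, rng)
            rev = sample_reversibilities(constraints, thermo, rng)
            r_elem = sample_branching(mech, thermo.v_ref, rng)
            k = assemble_rate_constants(mech, e_ref, rev, r_elem, thermo.sgn)
            sample = KineticSample(
                mechanism=mech,
                thermo=thermo,
                e_ref=e_ref,
                reversibilities=rev,
                r_elem=r_elem,
                k_scaled=k,
                seed_info=(seed if seed is not None else 0, draw_index),
            )
        else:
            from .allosteric import sample_regulatory

            sample = sample_regulatory(
                mech, thermo, allosteric_config, constraints, rng,
                seed_info=(seed if seed is not None else 0, draw_index),
            )
        if accuracy_check(sample, epsilon):
            return sample
        sample_parameter_set.rejections += 1
        logger.debug("rejected sample (accuracy check), retrying")
    raise RuntimeError("accuracy check failed repeatedly; mechanism ill-conditioned")


sample_parameter_set.rejections = 0


def sample_ensemble(
    mech: Mechanism,
    thermo: ThermoReference,
    n: int,
    seed: int,
    allosteric_config=None,
    epsilon: float = DEFAULT_EPSILON,
) -> list[KineticSample]:
    """Draw ``n`` accepted samples with one reproducible substream per draw."""
    root = np.random.SeedSequence(seed)
    children = root.spawn(n)
    out = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        out.append(
            sample_parameter_set(
                mech, thermo, allosteric_config, rng,
                seed=seed, draw_index=i, epsilon=epsilon,
            )
        )
    return out
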