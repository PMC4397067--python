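"""Steady-state rate law evaluation for a protomer.

Given the scaled rate constants of a mechanism (interleaved
forward/reverse per step, 1/min) and normalized reactant concentrations
(reference = 1), the enzyme-intermediate fractions at quasi steady state
solve a linear mass-balance system with the closure sum(e) = 1.  The net
velocity is measured on the reference-product cut: the summed net rates
of all steps releasing (minus those binding) the reference product.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping

import numpy as np

from .mechanism import BINDING, RELEASE, Mechanism

__all__ = ["ConcentrationState", "SteadyStateResult", "steady_state", "velocity"]


@dataclass(frozen=True)
class ConcentrationState:
    """Normalized metabolite and effector concentrations (reference = 1).

    Metabolites or effectors not listed are taken at their reference
    value of 1.
    """

    x: Mapping[str, float] = field(default_factory=dict)
    effectors: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, v in list(self.x.items()) + list(self.effectors.items()):
            if v < 0:
                raise ValueError(f"negative concentration for {name!r}: {v}")

    def conc(self, met: str) -> float:
        return float(self.x.get(met, 1.0))

    def effector(self, name: str) -> float:
        return float(self.effectors.get(name, 1.0))


REFERENCE_STATE = ConcentrationState()


@dataclass(frozen=True)
class SteadyStateResult:
    """Intermediate fractions and net velocity at one concentration state."""

    fractions: np.ndarray
    velocity: float
    free_enzyme_fraction: float


@lru_cache(maxsize=None)
def _index_arrays(mech: Mechanism):
    """Per-mechanism step index arrays, cached on the (frozen) mechanism."""
    ridx = np.array([mech.intermediate_index(s.reactant) for s in mech.steps])
    pidx = np.array([mech.intermediate_index(s.product) for s in mech.steps])
    met = [s.metabolite for s in mech.steps]
    is_bind = np.array([s.role == BINDING for s in mech.steps])
    is_rel = np.array([s.role == RELEASE for s in mech.steps])
    ref_sign = np.zeros(mech.q)
    for j, s in enumerate(mech.steps):
        if s.metabolite == mech.reference_product:
            ref_sign[j] = 1.0 if s.role == RELEASE else -1.0
    return ridx, pidx, met, is_bind, is_rel, ref_sign


def rate_coefficients(
    mech: Mechanism, k_scaled: np.ndarray, state: ConcentrationState
) -> tuple[np.ndarray, np.ndarray]:
    """First-order rate coefficients (a_fwd, a_rev) per step at the given state.

    Binding steps carry the metabolite concentration on the forward
    coefficient, release steps on the reverse (rebinding) coefficient.
    """
    k = np.asarray(k_scaled, dtype=float)
    if k.shape != (2 * mech.q,):
        raise ValueError(f"k_scaled must have length {2 * mech.q}")
    _, _, met, is_bind, is_rel, _ = _index_arrays(mech)
    a_fwd = k[0::2].copy()
    a_rev = k[1::2].copy()
    for j in range(mech.q):
        if is_bind[j]:
            a_fwd[j] *= state.conc(met[j])
        elif is_rel[j]:
            a_rev[j] *= state.conc(met[j])
    return a_fwd, a_rev


def steady_state(
    mech: Mechanism, k_scaled: np.ndarray, state: ConcentrationState = REFERENCE_STATE
) -> SteadyStateResult:
    """Solve the quasi-steady-state system for the intermediate fractions.

    One mass balance (any; they are linearly dependent since the column
    sums of the rate matrix vanish) is replaced by the normalization row
    sum(e) = 1.  Zero concentrations are legal: the limiting linear
    system is solved directly.
    """
    ridx, pidx, _, _, _, ref_sign = _index_arrays(mech)
    a_fwd, a_rev = rate_coefficients(mech, k_scaled, state)
    p = mech.p
    a = np.zeros((p, p))
    np.add.at(a, (pidx, ridx), a_fwd)
    np.subtract.at(a, (ridx, ridx), a_fwd)
    np.add.at(a, (ridx, pidx), a_rev)
    np.subtract.at(a, (pidx, pidx), a_rev)
    b = np.zeros(p)
    a[0, :] = 1.0
    b[0] = 1.0
    try:
        e = np.linalg.solve(a, b)
    except np.linalg.LinAlgError:
        e, *_ = np.linalg.lstsq(a, b, rcond=None)
    e = np.where(np.abs(e) < 1e-14, np.abs(e), e)
    v = float(ref_sign @ (a_fwd * e[ridx] - a_rev * e[pidx]))
    return SteadyStateResult(
        fractions=e,
        velocity=v,
        free_enzyme_fraction=float(e[mech.intermediate_index(mech.free_enzyme)]),
    )


def velocity(
    mech: Mechanism, k_scaled: np.ndarray, state: ConcentrationState = REFERENCE_STATE
) -> float:
    """Net velocity (mM/min) on the reference-product cut."""
    return steady_state(mech, k_scaled, state).velocity
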