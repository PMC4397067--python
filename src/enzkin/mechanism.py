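"""Enzyme mechanism representation: elementary steps, stoichiometry, cycles.

A mechanism is a set of reversible elementary steps between enzyme
intermediates (free enzyme, binary/ternary complexes, conformers).  Each
step optionally binds or releases one metabolite.  From the step list we
derive the pattern stoichiometric matrix ``S_pattern`` (intermediates x
steps, net elementary fluxes), enumerate the fundamental cycles that
convert the full substrate set into the full product set once, and build
the cycle constraint matrix ``omega_rev`` that ties the step
reversibilities to the overall Gibbs free-energy difference.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml

__all__ = [
    "ElementaryStep",
    "Mechanism",
    "ThermoReference",
    "CycleConstraints",
    "MechanismError",
    "parse_mechanism",
    "build_cycle_constraints",
]

#: default absolute temperature [K]
DEFAULT_TEMPERATURE = 298.15
#: universal gas constant [kJ/(mol K)]
GAS_CONSTANT = 8.314e-3

BINDING = "binding"
RELEASE = "release"
ISOMERIZATION = "isomerization"


class MechanismError(ValueError):
    """Raised for structurally invalid mechanisms or thermodynamic references."""


@dataclass(frozen=True)
class ElementaryStep:
    """One reversible elementary reaction between two enzyme intermediates.

    The forward direction is the declared left-to-right direction.  A
    *binding* step consumes ``metabolite`` in the forward direction, a
    *release* step produces it; an isomerization/catalysis step involves
    no metabolite.
    """

    index: int
    reactant: str
    product: str
    metabolite: Optional[str] = None
    role: str = ISOMERIZATION

    def __post_init__(self) -> None:
        if self.reactant == self.product:
            raise MechanismError(
                f"step {self.index}: self-loop {self.reactant!r} <-> {self.product!r}"
            )
        if (self.metabolite is None) != (self.role == ISOMERIZATION):
            raise MechanismError(
                f"step {self.index}: role {self.role!r} inconsistent with "
                f"metabolite {self.metabolite!r}"
            )

    def as_text(self) -> str:
        """Serialize back to the ``X <-> Y [+ m]`` spec-file form."""
        if self.role == BINDING:
            return f"{self.reactant} + {self.metabolite} <-> {self.product}"
        if self.role == RELEASE:
            return f"{self.reactant} <-> {self.product} + {self.metabolite}"
        return f"{self.reactant} <-> {self.product}"


@dataclass(frozen=True)
class ThermoReference:
    """Thermodynamic anchor of the parameterization.

    The reference state is a non-equilibrium steady state with flux
    ``v_ref`` (mM/min) and Gibbs free-energy difference ``delta_gr``
    (kJ/mol); the reaction must run downhill in its net direction, i.e.
    ``delta_gr * sign(v_ref) < 0``.
    """

    delta_gr: float
    v_ref: float
    temperature: float = DEFAULT_TEMPERATURE
    gas_constant: float = GAS_CONSTANT

    def __post_init__(self) -> None:
        if self.delta_gr == 0.0:
            raise MechanismError("delta_gr must be nonzero (non-equilibrium reference)")
        if self.v_ref == 0.0:
            raise MechanismError("v_ref must be nonzero")
        if self.delta_gr * self.sgn >= 0.0:
            raise MechanismError(
                "delta_gr and v_ref must have opposite signs "
                f"(got delta_gr={self.delta_gr}, v_ref={self.v_ref})"
            )
        if self.temperature <= 0.0:
            raise MechanismError("temperature must be positive")

    @property
    def sgn(self) -> int:
        return 1 if self.v_ref > 0 else -1

    @property
    def rt(self) -> float:
        """R*T in kJ/mol."""
        return self.gas_constant * self.temperature

    @property
    def dgr_rt(self) -> float:
        """delta_Gr / RT (dimensionless)."""
        return self.delta_gr / self.rt

    @property
    def cycle_sum(self) -> float:
        """sgn(v_ref) * delta_Gr / RT — the required cycle sum of ln(R_i)."""
        return self.sgn * self.dgr_rt


_STEP_RE = re.compile(r"^\s*(.+?)\s*<->\s*(.+?)\s*$")


def _parse_side(side: str, intermediates: Sequence[str]) -> tuple[str, Optional[str]]:
    tokens = [t.strip() for t in side.split("+")]
    if not 1 <= len(tokens) <= 2 or any(not t for t in tokens):
        raise MechanismError(f"cannot parse step side {side!r}")
    inter = [t for t in tokens if t in intermediates]
    mets = [t for t in tokens if t not in intermediates]
    if len(inter) != 1:
        raise MechanismError(
            f"step side {side!r} must name exactly one intermediate "
            f"(declared: {list(intermediates)})"
        )
    return inter[0], (mets[0] if mets else None)


@dataclass(frozen=True)
class Mechanism:
    """A reaction pattern: intermediates, metabolites and elementary steps.

    ``intermediates[0]`` is conventionally the free enzyme unless
    ``free_enzyme`` says otherwise.  ``reference_product`` names the
    metabolite whose net release defines the reaction velocity.
    """

    name: str
    intermediates: tuple[str, ...]
    substrates: tuple[str, ...]
    products: tuple[str, ...]
    steps: tuple[ElementaryStep, ...]
    reference_product: str
    free_enzyme: str = ""

    def __post_init__(self) -> None:
        if not self.free_enzyme:
            object.__setattr__(self, "free_enzyme", self.intermediates[0])
        self._validate()

    # -- derived structure -------------------------------------------------

    @property
    def p(self) -> int:
        """Number of enzyme intermediates."""
        return len(self.intermediates)

    @property
    def q(self) -> int:
        """Number of elementary steps."""
        return len(self.steps)

    @property
    def metabolites(self) -> tuple[str, ...]:
        return self.substrates + self.products

    def intermediate_index(self, name: str) -> int:
        return self.intermediates.index(name)

    @property
    def s_pattern(self) -> np.ndarray:
        """Pattern stoichiometric matrix (p x q) over net elementary fluxes."""
        s = np.zeros((self.p, self.q), dtype=int)
        for j, st in enumerate(self.steps):
            s[self.intermediate_index(st.reactant), j] = -1
            s[self.intermediate_index(st.product), j] = 1
        return s

    @property
    def nullity(self) -> int:
        """Dimension of the null space of S_pattern (= q - p + 1)."""
        return self.q - np.linalg.matrix_rank(self.s_pattern)

    # -- validation --------------------------------------------------------

    def _validate(self) -> None:
        if len(set(self.intermediates)) != self.p:
            raise MechanismError("duplicate intermediate names")
        if self.free_enzyme not in self.intermediates:
            raise MechanismError(f"free enzyme {self.free_enzyme!r} not an intermediate")
        if not self.steps:
            raise MechanismError("mechanism has no steps")
        seen = set()
        for st in self.steps:
            for node in (st.reactant, st.product):
                if node not in self.intermediates:
                    raise MechanismError(f"step {st.index}: unknown intermediate {node!r}")
            key = (st.reactant, st.product, st.metabolite, st.role)
            if key in seen:
                raise MechanismError(f"duplicate step {st.as_text()!r}")
            seen.add(key)
            if st.metabolite is not None and st.metabolite not in self.metabolites:
                raise MechanismError(
                    f"step {st.index}: metabolite {st.metabolite!r} is neither a "
                    "declared substrate nor product"
                )
        if self.reference_product not in self.products:
            raise MechanismError(
                f"reference product {self.reference_product!r} not in products"
            )
        # connectivity of the intermediate graph (undirected)
        adj: dict[str, set[str]] = {i: set() for i in self.intermediates}
        for st in self.steps:
            adj[st.reactant].add(st.product)
            adj[st.product].add(st.reactant)
        stack, seen_nodes = [self.intermediates[0]], {self.intermediates[0]}
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen_nodes:
                    seen_nodes.add(nb)
                    stack.append(nb)
        if len(seen_nodes) != self.p:
            raise MechanismError("intermediate graph is disconnected")
        if np.linalg.matrix_rank(self.s_pattern) != self.p - 1:
            raise MechanismError("rank(S_pattern) != p - 1")
        consumed = {m for st in self.steps if st.role == BINDING for m in [st.metabolite]}
        produced = {m for st in self.steps if st.role == RELEASE for m in [st.metabolite]}
        for s in self.substrates:
            if s not in consumed:
                raise MechanismError(f"substrate {s!r} is never bound")
        for pr in self.products:
            if pr not in produced:
                raise MechanismError(f"product {pr!r} is never released")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "intermediates": list(self.intermediates),
            "substrates": list(self.substrates),
            "products": list(self.products),
            "steps": [st.as_text() for st in self.steps],
            "reference_product": self.reference_product,
            "free_enzyme": self.free_enzyme,
        }

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)


def parse_mechanism(spec: dict | str) -> Mechanism:
    """Build a validated :class:`Mechanism` from a spec mapping or YAML text.

    The spec lists ``intermediates``, ``substrates``, ``products``, a
    ``steps`` list of ``"X <-> Y [+ m]"`` strings (metabolite on the left
    side = binding, on the right side = release) and a
    ``reference_product``.  Ordering of intermediates and steps follows
    declaration order, so parse -> serialize -> parse round-trips exactly.
    """
    if isinstance(spec, str):
        spec = yaml.safe_load(spec)
    intermediates = tuple(spec["intermediates"])
    substrates = tuple(spec["substrates"])
    products = tuple(spec["products"])
    steps = []
    for idx, text in enumerate(spec["steps"]):
        m = _STEP_RE.match(text)
        if m is None:
            raise MechanismError(f"cannot parse step {text!r}")
        lhs, rhs = m.group(1), m.group(2)
        reactant, met_l = _parse_side(lhs, intermediates)
        product, met_r = _parse_side(rhs, intermediates)
        if met_l is not None and met_r is not None:
            raise MechanismError(f"step {text!r}: metabolite on both sides")
        if met_l is not None:
            steps.append(ElementaryStep(idx, reactant, product, met_l, BINDING))
        elif met_r is not None:
            steps.append(ElementaryStep(idx, reactant, product, met_r, RELEASE))
        else:
            steps.append(ElementaryStep(idx, reactant, product))
    return Mechanism(
        name=spec.get("name", "mechanism"),
        intermediates=intermediates,
        substrates=substrates,
        products=products,
        steps=tuple(steps),
        reference_product=spec["reference_product"],
        free_enzyme=spec.get("free_enzyme", intermediates[0]),
    )


@dataclass(frozen=True)
class CycleConstraints:
    """Fundamental cycles of a mechanism and the reversibility constraint matrix.

    Each row of ``omega_rev`` is the 0/1 indicator of one fundamental
    cycle over the q steps; for every sampled reversibility vector the
    cycle sums of ln(R) must all equal sgn(v_ref) * dGr / RT.
    """

    cycles: tuple[tuple[int, ...], ...]
    omega_rev: np.ndarray = field(repr=False)

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)

    @property
    def is_compulsory_order(self) -> bool:
        """True when a single cycle traverses every step (ordered/ping-pong)."""
        return self.n_cycles == 1 and bool(np.all(self.omega_rev == 1))


def _fundamental_cycles(mech: Mechanism) -> list[tuple[int, ...]]:
    """Enumerate simple directed cycles through the free enzyme that execute
    the overall reaction stoichiometry exactly once.

    DFS over step edges in their forward orientation; nodes are visited at
    most once per path.  A closed path qualifies when every substrate is
    bound exactly once and every product released exactly once.
    """
    out_steps: dict[str, list[ElementaryStep]] = {i: [] for i in mech.intermediates}
    for st in mech.steps:
        out_steps[st.reactant].append(st)

    target_bind = {s: 1 for s in mech.substrates}
    target_rel = {p: 1 for p in mech.products}
    start = mech.free_enzyme
    cycles: list[tuple[int, ...]] = []

    def consume(counts: dict[str, int], st: ElementaryStep) -> Optional[dict[str, int]]:
        if st.role == ISOMERIZATION:
            return counts
        new = dict(counts)
        key = st.metabolite
        assert key is not None
        if key not in new or new[key] == 0:
            return None  # would over-consume / over-produce
        new[key] -= 1
        return new

    def dfs(node: str, visited: set[str], path: list[int],
            bind_left: dict[str, int], rel_left: dict[str, int]) -> None:
        for st in out_steps[node]:
            nb = consume(bind_left, st) if st.role == BINDING else bind_left
            rl = consume(rel_left, st) if st.role == RELEASE else rel_left
            if nb is None or rl is None:
                continue
            if st.product == start:
                if path and all(v == 0 for v in nb.values()) and all(
                    v == 0 for v in rl.values()
                ):
                    cycles.append(tuple(path + [st.index]))
                continue
            if st.product in visited:
                continue
            dfs(st.product, visited | {st.product}, path + [st.index], nb, rl)

    dfs(start, {start}, [], dict(target_bind), dict(target_rel))
    return sorted(set(cycles))


def build_cycle_constraints(mech: Mechanism) -> CycleConstraints:
    """Enumerate fundamental cycles and assemble ``omega_rev``.

    Raises :class:`MechanismError` if the mechanism admits no complete
    cycle (malformed pattern).
    """
    cycles = _fundamental_cycles(mech)
    if not cycles:
        raise MechanismError(
            f"mechanism {mech.name!r} has no cycle executing the overall reaction"
        )
    omega = np.zeros((len(cycles), mech.q))
    for r, cyc in enumerate(cycles):
        omega[r, list(cyc)] = 1.0
    return CycleConstraints(cycles=tuple(cycles), omega_rev=omega)
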