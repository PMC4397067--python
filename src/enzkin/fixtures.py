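"""Built-in case-study mechanisms and synthetic reference data.

Every mechanism used in the ensemble studies ships as a named fixture so
all analyses run without external inputs: compulsory-order Uni-Uni /
Bi-Bi / Ter-Ter chains, the ping-pong and random-order bimolecular
mechanisms, the branched random-order Uni-Bi pattern, the mnemonic
(conformational-memory) glucokinase mechanism and the allosterically
activated PEP carboxylase.  A synthetic saturation-curve generator
stands in for external experimental curves in the rejection-filter demo.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .allosteric import AllostericConfig, AllostericSite, Effector
from .mechanism import Mechanism, ThermoReference, parse_mechanism
from .rate_law import ConcentrationState

__all__ = [
    "FIXTURE_NAMES",
    "make_fixture",
    "glucokinase_protocol",
    "synth_reference_curve",
]

#: thermodynamic protocol for the glucokinase cooperativity study:
#: strongly exergonic reference (initial-velocity conditions) and the
#: experimental liver-cell reference flux
GLUCOKINASE_DELTA_GR = -100.0  # kJ/mol
GLUCOKINASE_V_REF = 0.064  # mM/min


def _mech(name, intermediates, substrates, products, steps, reference_product):
    return parse_mechanism(
        {
            "name": name,
            "intermediates": intermediates,
            "substrates": substrates,
            "products": products,
            "steps": steps,
            "reference_product": reference_product,
        }
    )


def _ordered_uni_uni() -> Mechanism:
    return _mech(
        "ordered_uni_uni",
        ["E", "EA", "EP"],
        ["a"], ["p"],
        ["E + a <-> EA", "EA <-> EP", "EP <-> E + p"],
        "p",
    )


def _ordered_bi_bi() -> Mechanism:
    return _mech(
        "ordered_bi_bi",
        ["E", "EA", "EAB", "EPQ", "EQ"],
        ["a", "b"], ["p", "q"],
        [
            "E + a <-> EA",
            "EA + b <-> EAB",
            "EAB <-> EPQ",
            "EPQ <-> EQ + p",
            "EQ <-> E + q",
        ],
        "p",
    )


def _ordered_ter_ter() -> Mechanism:
    return _mech(
        "ordered_ter_ter",
        ["E", "EA", "EAB", "EABC", "EPQR", "EQR", "ER"],
        ["a", "b", "c"], ["p", "q", "r"],
        [
            "E + a <-> EA",
            "EA + b <-> EAB",
            "EAB + c <-> EABC",
            "EABC <-> EPQR",
            "EPQR <-> EQR + p",
            "EQR <-> ER + q",
            "ER <-> E + r",
        ],
        "p",
    )


def _ping_pong_bi_bi() -> Mechanism:
    # substituted-enzyme mechanism: first product leaves before the
    # second substrate binds; F is the covalently modified enzyme
    return _mech(
        "ping_pong_bi_bi",
        ["E", "EA", "FP", "F", "FB", "EQ"],
        ["a", "b"], ["p", "q"],
        [
            "E + a <-> EA",
            "EA <-> FP",
            "FP <-> F + p",
            "F + b <-> FB",
            "FB <-> EQ",
            "EQ <-> E + q",
        ],
        "p",
    )


def _random_bi_bi() -> Mechanism:
    # random substrate binding, ordered product release
    return _mech(
        "random_bi_bi",
        ["E", "EA", "EB", "EAB", "EQ"],
        ["a", "b"], ["p", "q"],
        [
            "E + a <-> EA",
            "E + b <-> EB",
            "EA + b <-> EAB",
            "EB + a <-> EAB",
            "EAB <-> EQ + p",
            "EQ <-> E + q",
        ],
        "p",
    )


def _random_uni_bi() -> Mechanism:
    # ternary complex EPQ splits to either EP or EQ
    return _mech(
        "random_uni_bi",
        ["E", "EA", "EPQ", "EP", "EQ"],
        ["a"], ["p", "q"],
        [
            "E + a <-> EA",
            "EA <-> EPQ",
            "EPQ <-> EP + q",
            "EP <-> E + p",
            "EPQ <-> EQ + p",
            "EQ <-> E + q",
        ],
        "p",
    )


def _glucokinase_mnemonic() -> Mechanism:
    # conformational-memory mechanism: a slow transition between the
    # high-affinity free enzyme E and the low-affinity conformer E*
    # competes with direct glucose binding, producing kinetic
    # cooperativity for glucose in a monomeric enzyme
    return _mech(
        "glucokinase_mnemonic",
        ["E", "E*", "E-glc", "E-glc-atp", "E-g6p-adp", "E-adp"],
        ["glc", "atp"], ["g6p", "adp"],
        [
            "E + glc <-> E-glc",
            "E <-> E*",
            "E* + glc <-> E-glc",
            "E-glc + atp <-> E-glc-atp",
            "E-glc-atp <-> E-g6p-adp",
            "E-g6p-adp <-> E-adp + g6p",
            "E-adp <-> E + adp",
        ],
        "g6p",
    )


def _pepc() -> Mechanism:
    # ordered Bi-Bi: PEP binds first, oxaloacetate released last
    return _mech(
        "pepc",
        ["E", "E-pep", "E-pep-hco3", "E-oaa-pi", "E-oaa"],
        ["pep", "hco3"], ["pi", "oaa"],
        [
            "E + pep <-> E-pep",
            "E-pep + hco3 <-> E-pep-hco3",
            "E-pep-hco3 <-> E-oaa-pi",
            "E-oaa-pi <-> E-oaa + pi",
            "E-oaa <-> E + oaa",
        ],
        "oaa",
    )


def _pepc_allosteric() -> AllostericConfig:
    # tetramer with two activator sites (FBP-type and acetyl-CoA-type)
    # plus one inhibitor site (aspartate, malate); inhibitors are
    # declared for completeness and set to zero in scenario evaluations
    return AllostericConfig(
        n=4,
        sites=(
            AllostericSite("fbp_site", (Effector("fbp", "activator"),)),
            AllostericSite("accoa_site", (Effector("accoa", "activator"),)),
            AllostericSite(
                "inhibitor_site",
                (Effector("asp", "inhibitor"), Effector("mal", "inhibitor")),
            ),
        ),
    )


_CATALOG = {
    "ordered_uni_uni": _ordered_uni_uni,
    "ordered_bi_bi": _ordered_bi_bi,
    "ordered_ter_ter": _ordered_ter_ter,
    "ping_pong_bi_bi": _ping_pong_bi_bi,
    "random_bi_bi": _random_bi_bi,
    "random_uni_bi": _random_uni_bi,
    "glucokinase_mnemonic": _glucokinase_mnemonic,
    "pepc": _pepc,
}

FIXTURE_NAMES = tuple(sorted(_CATALOG))


def make_fixture(name: str) -> tuple[Mechanism, Optional[AllostericConfig]]:
    """Return a validated built-in mechanism (+ allosteric config if any)."""
    try:
        mech = _CATALOG[name]()
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        ) from None
    config = _pepc_allosteric() if name == "pepc" else None
    return mech, config


def glucokinase_protocol() -> ThermoReference:
    """Thermodynamic reference of the glucokinase cooperativity study."""
    return ThermoReference(delta_gr=GLUCOKINASE_DELTA_GR, v_ref=GLUCOKINASE_V_REF)


def synth_reference_curve(
    sample,
    substrate: str,
    grid: np.ndarray,
    noise_sd: float,
    rng: np.random.Generator,
    *,
    base_state: Optional[ConcentrationState] = None,
) -> pd.DataFrame:
    """Noisy synthetic saturation curve from a known parameter set.

    Evaluates the sample's velocity across ``grid`` (normalized
    substrate concentrations; co-reactants from ``base_state``) and adds
    i.i.d. Gaussian noise with standard deviation ``noise_sd`` (absolute,
    mM/min).  Returns a table with columns concentration / velocity / sd,
    the format consumed by the rejection filter.
    """
    base = base_state if base_state is not None else ConcentrationState()
    vels = []
    for g in np.asarray(grid, dtype=float):
        x = dict(base.x)
        x[substrate] = g
        vels.append(sample.velocity(ConcentrationState(x=x, effectors=base.effectors)))
    vels = np.asarray(vels)
    noisy = vels + rng.normal(0.0, noise_sd, size=vels.shape) if noise_sd > 0 else vels
    return pd.DataFrame(
        {
            "concentration": np.asarray(grid, dtype=float),
            "velocity": noisy,
            "sd": np.full(len(vels), float(noise_sd)),
        }
    )
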