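# Methods

## Scope and model

`enzkin` samples complete kinetic parameterizations of a single enzymatic
reaction from minimal reference data: the catalytic mechanism written as
reversible elementary steps, a reference steady-state flux `v_ref`
(mM/min) and the Gibbs free-energy difference of the reaction `ΔG_r`
(kJ/mol) at that reference. All concentrations are normalized to the
reference state (every metabolite and effector concentration equals 1
there), so absolute metabolite and total-enzyme concentrations are never
required; rate constants are produced on the corresponding scaled basis
(1/min).

A parameter set for one protomer consists of three independently sampled
ingredients:

1. **Intermediate abundances** `ẽ` — uniform on the p-simplex
   (Dirichlet with unit hyper-parameters, built from unit-rate gamma
   variates normalized by their sum).
2. **Reversibilities** `R_i ∈ (0,1)` — the reverse/forward elementary
   flux ratio of each step at the reference, raised to sgn(`v_ref`).
   Microscopic reversibility, extended to the non-equilibrium steady
   state, requires `Σ ln R_i = sgn(v_ref)·ΔG_r/RT` along every
   *fundamental cycle* (a directed cycle through the free enzyme that
   turns over the full reaction stoichiometry exactly once). In scaled
   form `ln R̂ ∈ [0,1]` with `Ω_rev·ln R̂ = 1`: compulsory-order
   mechanisms (one cycle covering all steps) are drawn directly from the
   Dirichlet simplex; multi-cycle mechanisms draw Dirichlet lower bounds
   and solve a linear program maximizing `Σ ln R̂`, which lands on varying
   corners of the feasible polytope (HiGHS, deterministic pivoting;
   infeasible bound draws are resampled, cap 100).
3. **Branching vector** `r_elem` — non-negative net elementary fluxes in
   the null space of the pattern stoichiometric matrix, rescaled so the
   largest entry equals `|v_ref|`. Weights are drawn uniformly on [0,1]
   per fundamental-cycle indicator vector (these indicators span the null
   space for every shipped mechanism); exact zeros are nudged to
   `1e-12·|v_ref|` so the assembly below stays finite.

The scaled rate constants follow exactly as
`k̃ = P(ẽ)⁻¹ · Γ(R) · r_elem`, where `P` is diagonal with the abundance
feeding each unidirectional flux and `Γ_fwd = 1/(1−R^sgn)`,
`Γ_rev = R^sgn/(1−R^sgn)` split each net flux into its forward and
reverse components. By construction every accepted set reproduces
`v_ref` at the all-ones state; an accuracy check `|v−v_ref| < ε`
(default `ε = 1e-8` mM/min) guards against numerical degeneracies and in
practice rejects far less than 0.01% of draws.

Velocities and intermediate fractions at arbitrary concentrations come
from a direct numerical solve of the quasi-steady-state linear system
with the closure `Σ ẽ = 1` substituted for one (redundant) balance —
the same object King–Altman’s schematic method evaluates symbolically,
which serves as an independent oracle in the tests for small mechanisms.
Velocity is measured on the reference-product cut (net rate of all steps
releasing, minus those binding, the designated reference product), which
is well defined for branched patterns and equals the flux through any
other graph cut at steady state.

## Allosteric (generalized MWC) layer

Oligomers factorize as `v = n·v_R·Ψ` with
`Ψ = (1 + (v_T/v_R)·Q)/(1 + Q)`. Both conformations share one mechanism
topology with independent rate-constant sets. The sampling order is the
only one in which each quantity is available when needed: (i) abundances
for R and T; (ii) the allosteric constant
`L0 = ((ẽ_T0/ẽ_T1)/(ẽ_R0/ẽ_R1))^{n/2}` (symmetric subunit binding) from
the free and first-substrate-bound fractions, and scaled effector
dissociation constants `K̃ = ẽ_0/ẽ_1` from per-effector two-component
simplex draws; (iii) `Q_ref`, the activity ratio
`a_ref = v_T/v_R ~ U(0,1)` (overridable, e.g. 0 for an induced-fit,
catalytically dead T state) and hence `Ψ_ref`; (iv) the reference-flux
split `v_R = v_ref/(n·Ψ_ref)`, `v_T = a_ref·v_R`; (v) per-conformation
reversibility/branching draws and rate-constant assembly. For
`a_ref = 0` the T conformation is parameterized against a vanishing
pseudo-flux (`1e-12·v_R`) so its intermediate fractions — which Q still
needs — remain defined, while its catalytic contribution is exactly zero.

Q multiplies `L0`, the free-enzyme fraction ratio
`ẽ_R0(x,k_R)/ẽ_T0(x,k_T)`, and one factor per allosteric site,
`(1 + Σ_inhibitors x_F/K̃_T)` over `(1 + Σ_activators x_F/K̃_R)`, all
raised to the n-th power. Each site saturates independently; activators
bind R and inhibitors T unless a per-effector flag relaxes that.
Declared effectors sit at normalized concentration 1 at the reference;
scenario evaluations may set them to 0 (absent).

`Ψ ≤ 1` holds at the reference by construction (`a_ref ≤ 1`). Away from
the reference the two conformations, being independently parameterized,
can transiently invert their activities, so the structural bound is
`Ψ(x) ∈ [min(1, v_T/v_R), max(1, v_T/v_R)]` pointwise; the tests assert
exactly that. This is a real feature of the reference-anchored
parameterization, not a numerical artifact.

## Analyses

**Elasticities.** Scaled central differences
`ε = (x̃/v)·(v(1+Δh)−v(1−Δh))/(2Δh)` with `Δh = 0.01` at the all-ones
reference.

**Macroscopic (Cleland) constants.** Turnover numbers and Michaelis
constants are evaluated as *exact saturating limits* of the elementary
network rather than large-number extrapolations: each saturated binding
step is contracted (its two intermediates merged; the unbound member's
share vanishes in the limit, so its other outgoing rates drop), and the
reduced steady state is solved. For compulsory-order mechanisms the
velocity is exactly hyperbolic in any single reactant, so Michaelis
constants follow from one evaluation at the reference concentration.
Elementary dissociation constants (`k̃_rev/k̃_fwd` per binding step) are
reported alongside. The reference-state Haldane identities hold to
machine precision with the classic constant combinations (verified in
tests): `K̃_A/K̃_P` for Uni-Uni; `K_iA·K̃_B/K̃_P·K_iQ` for ordered Bi-Bi;
the two-outer-dissociation analogue for ordered Ter-Ter; and the
squared-turnover all-Michaelis form for ping-pong. Random-order patterns
are rejected (no unambiguous Cleland set).

**Energetic decomposition.** `ΔG_r/RT` splits exactly into a catalytic
term `ln(k̃cat,−/k̃cat,+)` (Cleland turnover numbers) and a binding term
(the Haldane-paired sum of log dissociation/Michaelis constants,
computed as the exact remainder). The study-level statistic is the slope
of the per-`ΔG_r` median of each term against `ΔG_r/RT`, i.e. the
fraction of the thermodynamic drive attributable to saturation vs
turnover.

**Hill curves.** Local logit slope
`n_H(S) = d ln(v/(V_sat−v))/d ln S` by centered differences on a
log-spaced grid (default `1e-2…1e2` times reference, 60 points), under
initial-velocity conditions (products at 0, co-substrates at reference).
`V_sat` is taken from a far asymptotic evaluation (`1e4` × the top grid
point); anchoring `V_sat` to the top grid point itself would blow up the
logit near the anchor and report spuriously large slopes even for
hyperbolic kinetics. The estimator recovers pure Hill exponents
{0.5, 1, 2, 4} to ±0.01. Curves whose interior maximum exceeds the far
asymptote (apparent substrate inhibition) are flagged non-saturating and
masked where the logit is undefined. Classification: positive if
`n_H,max > 1+δ`, negative if `min n_H < 1−δ` without exceeding `1+δ`,
else none, with `δ = 1e-3`.

**Mnemonic transition statistic.** For conformational-memory mechanisms
the ratio of the forward to reverse rate constant of the low-to-high
affinity isomerization at the free enzyme; a ratio below 1 is counted as
a slow transition.

**Rejection (ABC) filtering.** Root-mean-square distance between a
sample's predicted saturation curve and a reference table
(concentration/velocity/sd); samples within a tolerance are kept.
Reference curves for demonstrations are synthetic — generated from a
known sample with additive Gaussian noise — since the package ships no
experimental data.

**Summaries.** Medians with empirical 2.5–97.5 percentile bands
(the package's reading of 95% "confidence regions").

## Defaults and units

| quantity | default | units | note |
|---|---|---|---|
| temperature | 298.15 | K | configurable per reference |
| gas constant | 8.314e-3 | kJ/(mol·K) | |
| `ΔG_r` | required, ≠ 0, downhill | kJ/mol | sgn(`v_ref`)·`ΔG_r` < 0 enforced |
| `v_ref` | required, ≠ 0 | mM/min | reverse-running references supported |
| accuracy ε | 1e-8 | mM/min | configurable |
| elasticity Δh | 0.01 | — | 1% perturbation |
| Hill grid | 1e-2…1e2, 60 pts | × reference | log-spaced |
| cooperativity δ | 1e-3 | — | dead band around n_H = 1 |
| glucokinase protocol | ΔG_r = −100, v_ref = 0.064 | kJ/mol, mM/min | initial-velocity study conditions |

## What the synthetic data emulate — and what they do not

The fixture catalog covers the canonical mechanism topologies (ordered
Uni-Uni/Bi-Bi/Ter-Ter, ping-pong, random-order Bi-Bi and Uni-Bi, the
mnemonic glucokinase scheme, and PEP carboxylase as an ordered Bi-Bi
tetramer with FBP- and acetyl-CoA-type activator sites plus
default-absent inhibitors). Synthetic reference curves add i.i.d.
Gaussian noise to a known sample's saturation curve. Real assay data
have correlated errors, instrument drift and concentration uncertainty,
and real enzymes deviate from strict MWC symmetry; passing tests
demonstrate internal consistency of the sampler and estimators under the
stated model, not fidelity to any particular experimental dataset.

## Known limitations and open choices

* Fundamental cycles are enumerated as simple directed cycles through
  the free enzyme executing the overall stoichiometry once, traversing
  every step in its declared forward orientation; mechanisms whose
  cycles would need reverse-oriented steps are out of scope (none of
  the shipped fixtures do).
* The branching-vector distribution is the one genuinely open
  ingredient of the formalism: "uniform weights yielding a non-negative
  combination" does not pin down a measure on the flux polytope. This
  package uses uniform [0,1] weights on the fundamental-cycle indicator
  basis. Ensemble statistics of *branched* mechanisms that hinge on the
  branch-flux split — notably the fraction of mnemonic-glucokinase
  samples classified cooperative and the mean Hill coefficient — are
  sensitive to this choice (cooperativity strengthens sharply as the
  conformational-branch flux shrinks); unbranched (compulsory-order)
  results are unaffected.
* Cleland constants, and hence the energetic decomposition, are defined
  only for compulsory-order mechanisms.
* The two MWC conformations are sampled independently; only the
  reference state constrains their relative activity (see the Ψ bound
  above).
* Flux-control-coefficient analysis and multi-enzyme assembly are out
  of scope.

## Problem sizes

The default test suite samples 300–1,200 sets per condition (enough for
the asserted tolerances given the medians' robustness), and
`scripts/acceptance.py` runs the full studies at 10,000 sets per
condition (7-point `ΔG_r` grid for the decomposition study, 3-point
far-from-equilibrium grid for elasticities); a complete acceptance run
takes under two minutes on one CPU.
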