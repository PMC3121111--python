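# Methods

## The model

`fluxtarget` identifies candidate drug targets in a metabolic network by
contrasting two constraint-based flux states of the same network: the
*pathologic* state, in which the diseased system still maximizes its biomass
output, and the *medication* state, in which the disease-causing metabolites
are forced back into clinically healthy ranges at minimal collateral
disturbance.

The network is bipartite: `m` metabolites and `n` irreversible reactions
(reversible reactions are split into forward/backward copies).  `S` (m×n)
holds reactant coefficients `s_ij`, `T` (n×m) product coefficients `t_ji`,
and the net stoichiometric matrix is `Snet = −S + Tᵀ`.  Beyond the usual
FBA flux vector `v`, the model carries an explicit *mass flow* `x_i` per
metabolite: the total rate at which metabolite `i` is turned over,

    x_i = Σ_j s_ij v_j   (over consuming reactions)
    x_i = Σ_j t_ji v_j   (over producing reactions)

with both equalities holding for intermediates, which is exactly the
steady-state mass balance.  Metabolites only consumed (sources) or only
produced (sinks) get the one definition that applies; isolated metabolites
are pinned to `x_i = 0` and kept with a warning (partially curated pathway
files are common).

### Stage 1 — pathologic LP

Reactions whose catalyzing enzymes are inhibited in the disease state are
removed first.  Then

    max  Σ_i w_i x_i
    s.t. structural rows above,  0 ≤ v_j ≤ U_j,  0 ≤ x_i ≤ q_i

where `w_i` are the objective weights (1 on biomass precursors, 0
elsewhere), `U_j` the flux capacities and `q_i` optional mass-flow caps
(default ∞, the conventional choice — capacities usually live on reactions).
The explicit mass-balance row for intermediates is redundant given the two
x-definitions but is emitted anyway: it costs nothing and makes infeasibility
diagnostics point at the metabolite, not at a pair of definitions.

### Stage 2 — medication LP

Given healthy ranges `[a_i, b_i]` and the disease set `P` (metabolites out
of range in the pathologic state), the medication state solves the standard
goal program

    min  Σ_{i∈N} w_i (d_i⁺ + d_i⁻)
    s.t. structural rows,  0 ≤ v_j ≤ U_j
         a_i ≤ x_i ≤ b_i                      i ∈ P   (hard)
         x_i − d_i⁺ ≤ b_i,  x_i + d_i⁻ ≥ a_i,  d_i± ≥ 0,  i ∈ N

`N` is every ranged metabolite outside `P`; unranged metabolites contribute
nothing (range `[0, ∞)`).  The optimal objective is the *side effect* of
the cure.  Deviations are clipped post-solve to their closed forms
`d⁺ = max(0, x−b)`, `d⁻ = max(0, a−x)`, which the optimum attains anyway;
complementarity `d⁺·d⁻ = 0` follows.  Range bounds are closed intervals —
the only LP-representable reading of a "strictly below" clinical threshold,
and the one consistent with optima sitting exactly on a bound.
Per-metabolite side-effect weights are accepted (default 1, a plain sum).
An optional lexicographic stage that re-maximizes biomass at the fixed
minimal side effect exists behind `maximize_biomass=True`; it is off by
default because the plain two-stage scheme has no biomass term in stage 2.

### Degeneracy and tie-breaks

Both LPs routinely have optimal faces, not vertices, and the target
identification step reads *coordinates* of the chosen optimum, so the choice
of vertex is part of the method, not a numerical detail.  The package pins
it down lexicographically:

* **Pathologic**: at the fixed optimal objective, *maximize* total flux
  `Σ_j v_j`.  A diseased network running at maximal output plausibly engages
  its parallel routes fully, and this is the conservative choice for target
  discovery — every route that could carry pathologic flux does, so no
  potentially changed reaction is hidden at zero.  (Under unbounded
  capacities this stage can be unbounded; the solver then falls back to the
  primary optimum it already has.)
* **Medication**: at the fixed minimal side effect, minimize the total flux
  adjustment `Σ_j |v_j − v⁰_j|` relative to the pathologic state — the
  minimal-intervention principle.  A drug should reroute as little flux as
  the cure requires; this also keeps the changed-reaction set small and
  stable, which is what the target report is built from.

A minimum-total-flux tie-break is available for both stages
(`tie_break="min_total_flux"`), and `tie_break=None` disables the second
stage.  Lexicographic stages are implemented by re-solving with the previous
objective pinned within a relative slack of 1e-9.

### Target identification

With pathologic `v⁰` and medication `v¹`:

1. changed reactions: `|v¹_j − v⁰_j| > tol` (absolute, default 1e-6; a
   relative mode exists but fluxes within one scenario share a scale);
2. subnetwork: changed reactions plus their reactants and products;
3. prune, in a single pass, every compound that no subnetwork reaction
   produces (they enter the subsystem from outside); an iterative
   fixed-point variant is behind `iterative_prune=True` but the single pass
   is the defined procedure and the default;
4. targets: reactions left with no reactants — the sources of the rerouted
   flux.  Each target reports its enzymes, `(v⁰, v¹, Δv)` as the dose
   proxy (enzyme activity correlates with flux, so Δv is the required
   activity change), an inhibition/activation label from the sign of Δv,
   and — as an engineering aid beyond the core procedure — any of its
   enzymes that also catalyze unchanged reactions (off-target risk).

`verify_targets` closes the loop: it re-solves the *pathologic* LP with
only the target fluxes pinned to their medication values and evaluates the
resulting mass flows against the ranges.  On the built-in illustrative
network this reproduces the medication optimum exactly (both scenarios).
On arbitrary networks pinning the targets alone need not force the disease
compounds into range — the re-solve maximizes biomass wherever freedom
remains — so verification failures are reported (warning + the implied
side effect), not asserted away.

## Numerical choices

All LPs are solved with HiGHS (`scipy.optimize.linprog`), solver defaults
(~1e-9 feasibility).  Package-level comparisons use 1e-6 absolute; values
printed to two decimals in reports are compared at 5e-3 in the test suite.
Infeasible medication models name the hard disease ranges; unbounded
pathologic models arise only when every capacity is infinite.

## The synthetic generator

`generate_network` draws layered directed-acyclic networks: metabolites are
assigned to `n_layers` layers, each reaction takes 1–3 reactants from layers
below a random split point and 1–3 products from layers above it, with
integer coefficients in `[1, max_coefficient]`.  Layering rules out cycles,
so a feasible nonzero flux state essentially always exists; each draw is
verified by solving the pathologic LP with uniform sink weights and
resampled (bounded retries) if the optimum is zero.  Defaults (12
metabolites, 8 reactions, 3 layers, coefficients ≤ 3, `U_j = 10`) mirror the
scale of the illustrative network.  All randomness flows from the integer
seed; generation uses integer draws only, so networks are bit-identical
across platforms.

`plant_disease_scenario` plants a ground-truthed instance: solve the
pathologic LP, pick a flowing sink as the disease compound, set its healthy
range to half its pathologic flow, and cap the other sinks at their
pathologic flows (so gratuitous rerouting shows up as side effect).  The
ground truth is the set of source reactions from which the disease compound
is reachable.  Identified targets *intersect* this set in every tested
seed, but are not always contained in it: balance adjustments can reroute
flux through branches not upstream of the disease compound, and the sources
of those branches legitimately surface as additional targets.  The tested
invariants are therefore `targets ⊆ changed` and
`targets ∩ ground-truth ≠ ∅`.

What the generator does not emulate: currency metabolites, realistic degree
distributions, compartments, reversibility at equilibrium, or regulatory
effects.  Passing property tests show the LP/graph machinery is correct on
feasible acyclic instances, not that the biology of any real pathway is
captured; real applications should supply curated pathway files.

## Known limitations

* The printed illustrative network carries one stoichiometric typo (R7); the
  built-in fixture uses the unique consistent correction `C6 + 3 C7 → 2 C11
  + 3 C12` and says so in its docstring.
* Real pathway studies (e.g. the purine-metabolism/hyperuricemia case) are
  supported through the generic network/scenario files; the purine pathway
  reaction list itself is not bundled, and the corresponding end-to-end
  checks run only when a user supplies `data/hyperuricemia_network.tsv` and
  `data/hyperuricemia_scenario.yaml`.
* Mass flows are rates, not concentrations; no kinetics, no gene–protein–
  reaction rules, no compartments, no SBML semantics.  Target sets depend on
  the tie-break policy wherever optima are degenerate — that policy is
  explicit, documented above, and switchable.
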