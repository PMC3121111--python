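# fluxtarget

Two-stage flux balance analysis (FBA) for identifying drug targets in
metabolic networks, with side effects accounted for quantitatively.

Diseases of metabolism often show up as a metabolite whose turnover (*mass
flow*) sits outside its clinically healthy range.  A drug should bring that
metabolite back into range — and disturb the rest of the metabolism as
little as possible.  `fluxtarget` formalizes both halves as linear programs
over a stoichiometric network model and then reads candidate targets off the
difference between the two solutions:

1. **Pathologic LP** — the diseased network still maximizes its biomass
   output: `max Σ w_i x_i` subject to steady-state mass balance,
   `x_i = Σ_j s_ij v_j = Σ_j t_ji v_j` (mass-flow definitions), and
   capacities `0 ≤ v_j ≤ U_j`, `0 ≤ x_i ≤ q_i`.  Yields `(v⁰, x⁰)`.
2. **Medication LP** — force each disease-causing metabolite `i ∈ P` into
   its healthy range `a_i ≤ x_i ≤ b_i` (hard), and minimize the **side
   effect** `Σ_{i∈N} (d_i⁺ + d_i⁻)`, the summed deviation of all other
   ranged metabolites from their healthy ranges.  Yields `(v¹, x¹)`.
3. **Target identification** — take the reactions with `v¹_j ≠ v⁰_j`, build
   their subnetwork, delete compounds no subnetwork reaction produces, and
   report the reactions left without reactants: the *sources* of the
   rerouted flux.  Their enzymes are the drug targets and `Δv_j = v¹_j −
   v⁰_j` is the dose proxy.

The audience is systems-biology and computational-pharmacology work on
curated disease pathways (the method was developed against a purine
metabolism / hyperuricemia pathway, where it recovers xanthine oxidase and
phosphoribosylpyrophosphate synthetase among the targets).

## Worked example

The package ships a 12-metabolite / 8-reaction illustrative network
(`toy_network()`), with biomass weights on C8, C9, C11, C12 and `U_j = 10`.
Note: one printed form of this network's reaction R7 contains a
stoichiometric typo; the fixture uses the unique consistent correction
`R7: C6 + 3 C7 → 2 C11 + 3 C12` (see `fluxtarget/fixtures.py`).

```python
>>> from fluxtarget import TwoStageFBA, toy_network
>>> network, config, ranges1, ranges2 = toy_network()
>>> res = TwoStageFBA(network, config, ranges1).fit()
>>> print(res.summary())
Two-stage FBA drug-target analysis
======================================================
Metabolites:   12    Reactions:    8
Pathologic objective (weighted mass flow): 91.25
Side effect (medication optimum):          3.66667
Changed reactions: 6    Targets: 3
------------------------------------------------------
Targets (dose proxy = required flux change):
  R2       E2               v0=    3.75  v1=       1 Δv=   -2.75  [inhibition]
  R3       E3               v0=      10  v1=       0 Δv=     -10  [inhibition]
  R4       E4               v0=       5  v1=       0 Δv=      -5  [inhibition]
------------------------------------------------------
Verification (targets pinned, pathologic re-solve): side effect 3.66667
```

Reading this: in the pathologic state the network runs at
`v⁰ = (10, 3.75, 10, 5, 5, 10, 1.25, 10)` and the disease compounds C11 and
C12 flow at 22.5 and 33.75 — far above their healthy ranges `[10, 15]` and
`[0, 1]`.  The medication optimum `v¹ = (10, 1, 0, 0, 5, 6.33, 0.33, 0)`
cures both at side effect 3.667: only C10 (healthy range `[10, 15]`) is left
deviating, at mass flow 6.33.  Inhibiting the enzymes of R2, R3, R4 down to
fluxes (1, 0, 0) suffices — the verification line re-solves the pathologic
model with just those three fluxes pinned and lands on the same state.  With
the relaxed scenario-2 ranges (`ranges2`) the same three targets cure the
disease at side effect 0.

The same pipeline is scriptable from the shell:

```sh
fluxtarget fixtures --out fx --toy
fluxtarget pipeline --network fx/toy_network.tsv --scenario fx/toy_scenario1.yaml --out run/
```

Network files are plain TSV (`reaction_id  equation  enzymes  flux_upper`,
one reaction per row, `2 C1 + C2 -> C5 + C6` grammar, `<->` for reversible);
scenarios are YAML (objective weights, capacities, healthy ranges, disease
compounds, inhibited enzymes).  Lower-level entry points
(`solve_pathologic`, `solve_medication`, `identify_targets`,
`verify_targets`) expose each stage separately, and
`generate_network` / `plant_disease_scenario` provide seeded random
instances with ground truth for benchmarking.

See `docs/methods.md` for the full model, the tie-break policy that makes
degenerate optima reproducible, and known limitations.

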