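"""Stage 2: the medication-state LP with side-effect minimization.

Medication must bring every disease-causing compound ``i ∈ P`` back into
its healthy range ``[a_i, b_i]`` (hard constraint) while disturbing the
rest of the metabolism as little as possible.  The disturbance — the *side
effect* — is the summed deviation of the non-disease ranged metabolites
``i ∈ N`` from their healthy ranges, written in the standard
goal-programming form with deviation variables:

    min  sum_{i in N} w_i (d_i+ + d_i-)
    s.t. structural rows of the network (balances and x-definitions)
         a_i <= x_i <= b_i                   i in P   (hard)
         x_i - d_i+ <= b_i,  x_i + d_i- >= a_i,  d_i± >= 0,   i in N
         0 <= v_j <= U_j

At the optimum ``d_i+ = max(0, x_i - b_i)`` and ``d_i- = max(0, a_i - x_i)``;
the solver clips the reported deviations to those closed forms.  A side
effect of zero means the disease is curable without pushing any ranged
metabolite out of its healthy window.

The side-effect optimum is often a face, not a vertex.  The default
lexicographic second stage selects, on that face, the solution of minimal
total flux adjustment ``sum_j |v_j - v0_j|`` relative to the pathologic
state — the minimal-intervention principle: a medication should reroute as
little flux as possible beyond what the cure requires.  This also keeps the
changed-reaction set (and hence the identified targets) small and stable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._lp import STATUS_OPTIMAL, LinearProgram, lexicographic_solve
from .network import MetabolicNetwork
from .pathologic import (
    TIE_BREAK_MIN_FLUX,
    FluxState,
    _extract_state,
    _v,
    _x,
    add_state_variables,
    apply_disease_knockouts,
    solve_pathologic,
)
from .scenario import ConfigurationError, HealthyRanges, ScenarioConfig

__all__ = ["MedicationSolution", "build_medication_lp", "solve_medication"]

TIE_BREAK_MIN_CHANGE = "min_change"


@dataclass(frozen=True)
class MedicationSolution:
    """Medication-state solution: flux state plus per-metabolite deviations
    and the total side effect."""

    state: FluxState
    dev_above: dict[str, float]
    dev_below: dict[str, float]
    side_effect: float

    @property
    def ok(self) -> bool:
        return self.state.ok

    @property
    def status(self) -> str:
        return self.state.status


def _dev_vars(mid: str) -> tuple[str, str]:
    return f"dplus[{mid}]", f"dminus[{mid}]"


def build_medication_lp(
    network: MetabolicNetwork, config: ScenarioConfig, ranges: HealthyRanges
) -> LinearProgram:
    """Assemble the stage-2 LP (see module docstring)."""
    if not ranges.disease:
        raise ConfigurationError("no disease-causing compound specified")
    known = set(network.metabolite_ids)
    missing = [p for p in ranges.disease if p not in known]
    if missing:
        raise ConfigurationError(f"disease compounds not in network: {missing}")
    lp = LinearProgram(sense="min")
    add_state_variables(lp, network, config)
    for mid in ranges.disease:
        a, b = ranges.ranges[mid]
        _, q = lp.bounds(_x(mid))
        lp.set_bounds(_x(mid), a, min(b, q))
    objective: dict[str, float] = {}
    for mid in ranges.non_disease:
        if mid not in known:
            continue
        a, b = ranges.ranges[mid]
        dplus, dminus = _dev_vars(mid)
        lp.add_variable(dplus, 0.0, np.inf)
        lp.add_variable(dminus, 0.0, np.inf)
        if np.isfinite(b):
            lp.add_constraint(f"soft_upper[{mid}]", {_x(mid): 1.0, dplus: -1.0}, -np.inf, b)
        lp.add_constraint(f"soft_lower[{mid}]", {_x(mid): 1.0, dminus: 1.0}, a, np.inf)
        w = ranges.weight(mid)
        objective[dplus] = w
        objective[dminus] = w
    lp.objective = objective
    return lp


def solve_medication(
    network: MetabolicNetwork,
    config: ScenarioConfig,
    ranges: HealthyRanges,
    *,
    reference: FluxState | None = None,
    tie_break: str | None = TIE_BREAK_MIN_CHANGE,
    maximize_biomass: bool = False,
    apply_knockouts: bool = True,
) -> MedicationSolution:
    """Solve the medication LP; returns a :class:`MedicationSolution`.

    ``reference`` is the pathologic state used by the minimal-change
    tie-break; if omitted it is computed on the fly.  ``maximize_biomass``
    inserts an optional intermediate lexicographic stage that, at the fixed
    minimal side effect, maximizes the pathologic biomass objective — an
    extension beyond the plain two-stage scheme, off by default.
    """
    if apply_knockouts:
        network = apply_disease_knockouts(network, config)
    lp = build_medication_lp(network, config, ranges)
    stages: list[tuple[str, dict[str, float]]] = [("min", dict(lp.objective))]
    if maximize_biomass:
        biomass = {
            _x(mid): float(w)
            for mid, w in config.objective_weights.items()
            if mid in set(network.metabolite_ids) and w != 0
        }
        stages.append(("max", biomass))
    if tie_break == TIE_BREAK_MIN_CHANGE:
        if reference is None:
            reference = solve_pathologic(network, config, apply_knockouts=False)
        if reference.ok:
            change_obj: dict[str, float] = {}
            ref = dict(zip(reference.reaction_ids, reference.v))
            for rid in network.reaction_ids:
                v0 = ref.get(rid, 0.0)
                e = f"change[{rid}]"
                lp.add_variable(e, 0.0, np.inf)
                # e >= |v - v0| via two half-planes
                lp.add_constraint(f"change_up[{rid}]", {_v(rid): 1.0, e: -1.0}, -np.inf, v0)
                lp.add_constraint(f"change_dn[{rid}]", {_v(rid): -1.0, e: -1.0}, -np.inf, -v0)
                change_obj[e] = 1.0
            stages.append(("min", change_obj))
        else:
            warnings.warn(
                "pathologic reference state unavailable; falling back to the "
                "minimum-total-flux tie-break",
                stacklevel=2,
            )
            stages.append(("min", {_v(r): 1.0 for r in network.reaction_ids}))
    elif tie_break == TIE_BREAK_MIN_FLUX:
        stages.append(("min", {_v(r): 1.0 for r in network.reaction_ids}))
    elif tie_break is not None:
        raise ValueError(f"unknown tie_break {tie_break!r}")
    sol = lexicographic_solve(lp, stages)
    state = _extract_state(network, sol)
    if not state.ok:
        detail = "; ".join(
            f"{mid} in [{ranges.ranges[mid][0]}, {ranges.ranges[mid][1]}]"
            for mid in ranges.disease
        )
        warnings.warn(
            f"medication LP {state.status}; hard disease ranges: {detail}",
            stacklevel=2,
        )
        return MedicationSolution(state=state, dev_above={}, dev_below={}, side_effect=float("nan"))
    dev_above: dict[str, float] = {}
    dev_below: dict[str, float] = {}
    side_effect = 0.0
    known = set(network.metabolite_ids)
    for mid in ranges.non_disease:
        if mid not in known:
            continue
        dplus, dminus = ranges.deviation(mid, state.mass_flow(mid))
        dev_above[mid] = dplus
        dev_below[mid] = dminus
        side_effect += ranges.weight(mid) * (dplus + dminus)
    return MedicationSolution(
        state=state, dev_above=dev_above, dev_below=dev_below, side_effect=side_effect
    )
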