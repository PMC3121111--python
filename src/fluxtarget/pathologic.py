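"""Stage 1: the pathologic-state flux/mass-flow LP.

In the disease state the network still produces as much biomass as it can,
so fluxes ``v_j`` and metabolite mass flows ``x_i`` are determined by

    max  sum_i w_i x_i
    s.t. sum_j t_{j,i} v_j - sum_j s_{i,j} v_j = 0     (intermediates)
         x_i = sum_j s_{i,j} v_j                       (consumed metabolites)
         x_i = sum_j t_{j,i} v_j                       (produced metabolites)
         0 <= v_j <= U_j,   0 <= x_i <= q_i

For an intermediate both x-definitions hold, which enforces the mass
balance implicitly; the explicit balance row is emitted anyway because the
redundancy is cheap and makes infeasibility diagnostics clearer.  Isolated
metabolites get ``x_i = 0``.

Maximum-mass-flow optima are frequently degenerate (parallel routes into a
capacity-limited sink).  For reproducibility the solver applies a
lexicographic second stage that, at the fixed optimal objective, maximizes
the total flux ``sum_j v_j`` — the vertex at which the pathologic network is
maximally engaged, the conservative picture of a disease state running hot.
``tie_break`` switches this to minimal total flux, or disables it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from ._lp import STATUS_OPTIMAL, LinearProgram, lexicographic_solve
from .network import (
    ROLE_CONSUMED_ONLY,
    ROLE_INTERMEDIATE,
    ROLE_ISOLATED,
    ROLE_PRODUCED_ONLY,
    MetabolicNetwork,
)
from .scenario import ScenarioConfig

__all__ = [
    "FluxState",
    "apply_disease_knockouts",
    "build_pathologic_lp",
    "solve_pathologic",
    "check_flux_state",
]

TIE_BREAK_MAX_FLUX = "max_total_flux"
TIE_BREAK_MIN_FLUX = "min_total_flux"


@dataclass(frozen=True)
class FluxState:
    """A solved network state: fluxes ``v``, mass flows ``x``, objective."""

    reaction_ids: tuple[str, ...]
    metabolite_ids: tuple[str, ...]
    v: np.ndarray
    x: np.ndarray
    objective: float
    status: str

    @property
    def ok(self) -> bool:
        return self.status == STATUS_OPTIMAL

    def flux(self, reaction_id: str) -> float:
        return float(self.v[self.reaction_ids.index(reaction_id)])

    def mass_flow(self, metabolite_id: str) -> float:
        return float(self.x[self.metabolite_ids.index(metabolite_id)])

    def flux_series(self) -> pd.Series:
        return pd.Series(self.v, index=list(self.reaction_ids), name="flux")

    def mass_flow_series(self) -> pd.Series:
        return pd.Series(self.x, index=list(self.metabolite_ids), name="mass_flow")


def apply_disease_knockouts(
    network: MetabolicNetwork, config: ScenarioConfig
) -> MetabolicNetwork:
    """Remove every reaction whose enzyme set intersects the inhibited set.

    An inhibited enzyme matching no reaction triggers a warning, not an
    error (curation lists often carry enzymes outside the modeled pathway).
    """
    inhibited = set(config.inhibited_enzymes)
    if not inhibited:
        return network
    catalyzed = {e for r in network.reactions for e in r.enzymes}
    unmatched = sorted(inhibited - catalyzed)
    if unmatched:
        warnings.warn(
            f"inhibited enzymes catalyze no reaction in the network: {unmatched}",
            stacklevel=2,
        )
    drop = [r.id for r in network.reactions if inhibited & set(r.enzymes)]
    return network.without_reactions(drop)


def _v(rid: str) -> str:
    return f"v[{rid}]"


def _x(mid: str) -> str:
    return f"x[{mid}]"


def add_state_variables(
    lp: LinearProgram, network: MetabolicNetwork, config: ScenarioConfig
) -> None:
    """Add v/x variables with capacity bounds and the shared structural rows
    (x-definitions and mass balances) used by both LP stages."""
    for r in network.reactions:
        lp.add_variable(_v(r.id), 0.0, config.flux_bound(r.id, network.flux_upper_hints.get(r.id)))
    for mid in network.metabolite_ids:
        lp.add_variable(_x(mid), 0.0, config.massflow_bound(mid))
    for i, mid in enumerate(network.metabolite_ids):
        role = network.roles[mid]
        consumption = {
            _v(rid): network.S[i, j]
            for j, rid in enumerate(network.reaction_ids)
            if network.S[i, j] != 0
        }
        production = {
            _v(rid): network.T[j, i]
            for j, rid in enumerate(network.reaction_ids)
            if network.T[j, i] != 0
        }
        if role in (ROLE_CONSUMED_ONLY, ROLE_INTERMEDIATE):
            lp.add_constraint(f"consume[{mid}]", {_x(mid): -1.0, **consumption}, 0.0, 0.0)
        if role in (ROLE_PRODUCED_ONLY, ROLE_INTERMEDIATE):
            lp.add_constraint(f"produce[{mid}]", {_x(mid): -1.0, **production}, 0.0, 0.0)
        if role == ROLE_INTERMEDIATE:
            balance = dict(production)
            for var, coef in consumption.items():
                balance[var] = balance.get(var, 0.0) - coef
            lp.add_constraint(f"balance[{mid}]", balance, 0.0, 0.0)
        if role == ROLE_ISOLATED:
            lp.add_constraint(f"isolated[{mid}]", {_x(mid): 1.0}, 0.0, 0.0)


def build_pathologic_lp(
    network: MetabolicNetwork, config: ScenarioConfig
) -> LinearProgram:
    """Assemble the stage-1 LP (see module docstring)."""
    lp = LinearProgram(sense="max")
    add_state_variables(lp, network, config)
    lp.objective = {
        _x(mid): float(w)
        for mid, w in config.objective_weights.items()
        if mid in set(network.metabolite_ids) and w != 0
    }
    return lp


def _extract_state(network: MetabolicNetwork, sol) -> FluxState:
    v = np.array([sol.values.get(_v(r), np.nan) for r in network.reaction_ids])
    x = np.array([sol.values.get(_x(m), np.nan) for m in network.metabolite_ids])
    return FluxState(
        reaction_ids=tuple(network.reaction_ids),
        metabolite_ids=tuple(network.metabolite_ids),
        v=v,
        x=x,
        objective=sol.objective,
        status=sol.status,
    )


def solve_pathologic(
    network: MetabolicNetwork,
    config: ScenarioConfig,
    *,
    tie_break: str | None = TIE_BREAK_MAX_FLUX,
    fixed_fluxes: Mapping[str, float] | None = None,
    apply_knockouts: bool = True,
) -> FluxState:
    """Solve the pathologic LP; returns a :class:`FluxState`.

    ``fixed_fluxes`` pins selected reactions to an exact flux value (used by
    target verification).  With ``apply_knockouts`` the disease knockouts of
    the config are applied first; the returned state is indexed by the
    *remaining* reactions.
    """
    if apply_knockouts:
        network = apply_disease_knockouts(network, config)
    lp = build_pathologic_lp(network, config)
    for rid, value in (fixed_fluxes or {}).items():
        if rid not in set(network.reaction_ids):
            raise KeyError(f"cannot fix flux of unknown reaction {rid!r}")
        lp.set_bounds(_v(rid), float(value), float(value))
    stages: list[tuple[str, dict[str, float]]] = [("max", dict(lp.objective))]
    total_flux = {_v(r): 1.0 for r in network.reaction_ids}
    if tie_break == TIE_BREAK_MAX_FLUX:
        stages.append(("max", total_flux))
    elif tie_break == TIE_BREAK_MIN_FLUX:
        stages.append(("min", total_flux))
    elif tie_break is not None:
        raise ValueError(f"unknown tie_break {tie_break!r}")
    sol = lexicographic_solve(lp, stages)
    state = _extract_state(network, sol)
    if not state.ok and sol.message:
        warnings.warn(f"pathologic LP {state.status}: {sol.message}", stacklevel=2)
    return state


def check_flux_state(
    network: MetabolicNetwork,
    config: ScenarioConfig,
    state: FluxState,
    tol: float = 1e-6,
) -> list[str]:
    """Independent feasibility audit of a solved state.

    Re-evaluates every bound, x-definition and mass balance directly from
    the reaction maps (not from any LP object) and returns the list of
    violations (empty list = feasible at ``tol``).
    """
    problems: list[str] = []
    for j, rid in enumerate(state.reaction_ids):
        u = config.flux_bound(rid, network.flux_upper_hints.get(rid))
        if not (-tol <= state.v[j] <= u + tol):
            problems.append(f"flux bound violated for {rid}: v={state.v[j]} not in [0, {u}]")
    for i, mid in enumerate(state.metabolite_ids):
        q = config.massflow_bound(mid)
        if not (-tol <= state.x[i] <= q + tol):
            problems.append(f"mass-flow bound violated for {mid}: x={state.x[i]} not in [0, {q}]")
    cons: dict[str, float] = {m: 0.0 for m in state.metabolite_ids}
    prod: dict[str, float] = {m: 0.0 for m in state.metabolite_ids}
    vmap = dict(zip(state.reaction_ids, state.v))
    for r in network.reactions:
        if r.id not in vmap:
            continue
        for met, c in r.reactants.items():
            cons[met] += c * vmap[r.id]
        for met, c in r.products.items():
            prod[met] += c * vmap[r.id]
    for i, mid in enumerate(state.metabolite_ids):
        role = network.roles[mid]
        if role in (ROLE_CONSUMED_ONLY, ROLE_INTERMEDIATE):
            if abs(state.x[i] - cons[mid]) > tol:
                problems.append(f"x[{mid}] != consumption ({state.x[i]} vs {cons[mid]})")
        if role in (ROLE_PRODUCED_ONLY, ROLE_INTERMEDIATE):
            if abs(state.x[i] - prod[mid]) > tol:
                problems.append(f"x[{mid}] != production ({state.x[i]} vs {prod[mid]})")
        if role == ROLE_INTERMEDIATE and abs(prod[mid] - cons[mid]) > tol:
            problems.append(f"mass balance violated for {mid} ({prod[mid]} vs {cons[mid]})")
        if role == ROLE_ISOLATED and abs(state.x[i]) > tol:
            problems.append(f"isolated metabolite {mid} has nonzero mass flow {state.x[i]}")
    return problems
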