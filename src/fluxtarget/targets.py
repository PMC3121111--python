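"""Drug-target identification from the pathologic/medication flux contrast.

The procedure reads the two solved states and works purely on the graph:

1. *Changed reactions*: every reaction with ``|v1_j - v0_j| > tol``.
2. *Subnetwork*: exactly the changed reactions plus the union of their
   reactants and products.
3. *Pruning*: one pass deleting every compound that is a product of no
   subnetwork reaction (those enter the subsystem from outside); reactions
   are kept even if their reactant map empties.
4. *Targets*: the reactions left with no reactants — the sources of the
   rerouted flux.  Their catalyzing enzymes are the drug targets, and the
   flux change ``Δv_j = v1_j - v0_j`` is the dose proxy (enzyme activity is
   correlated with reaction flux, so the required activity change scales
   with Δv).

A target with ``Δv < 0`` calls for inhibition of its enzymes, ``Δv > 0``
for activation.  :func:`verify_targets` closes the loop: re-solving the
pathologic model with only the target fluxes pinned to their medication
values must land the disease compounds in range at the same side effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .medication import MedicationSolution
from .network import MetabolicNetwork, Metabolite, Reaction
from .pathologic import FluxState, solve_pathologic
from .scenario import HealthyRanges, ScenarioConfig

__all__ = [
    "ChangedReaction",
    "Target",
    "TargetReport",
    "changed_reactions",
    "build_subnetwork",
    "prune_zero_indegree",
    "identify_targets",
    "verify_targets",
]

DEFAULT_TOL = 1e-6


@dataclass(frozen=True)
class ChangedReaction:
    reaction_id: str
    v0: float
    v1: float

    @property
    def delta(self) -> float:
        return self.v1 - self.v0


@dataclass(frozen=True)
class Target:
    """A source reaction of the rerouted flux and its enzymes."""

    reaction_id: str
    enzymes: tuple[str, ...]
    v0: float
    v1: float
    #: enzymes of this target that also catalyze reactions whose flux did
    #: NOT change — potential off-target flux effects when the enzyme is
    #: manipulated (engineering aid, not part of the core procedure).
    shared_enzymes: tuple[str, ...] = ()

    @property
    def delta(self) -> float:
        return self.v1 - self.v0

    @property
    def mode(self) -> str:
        return "inhibition" if self.delta < 0 else "activation"


@dataclass(frozen=True)
class TargetReport:
    changed: tuple[ChangedReaction, ...]
    subnetwork: MetabolicNetwork
    targets: tuple[Target, ...]
    side_effect: float

    @property
    def target_ids(self) -> tuple[str, ...]:
        return tuple(t.reaction_id for t in self.targets)

    @property
    def changed_ids(self) -> tuple[str, ...]:
        return tuple(c.reaction_id for c in self.changed)

    def changed_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c.reaction_id, c.v0, c.v1, c.delta) for c in self.changed],
            columns=["reaction_id", "v0", "v1", "delta"],
        )

    def target_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (t.reaction_id, ",".join(t.enzymes), t.v0, t.v1, t.delta, t.mode)
                for t in self.targets
            ],
            columns=["reaction_id", "enzymes", "v0", "v1", "delta", "mode"],
        )


def _as_flux_vector(v, ids) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(v, FluxState):
        return np.asarray(v.v, dtype=float), tuple(v.reaction_ids)
    if ids is None:
        raise ValueError("reaction_ids required when passing raw flux vectors")
    return np.asarray(v, dtype=float), tuple(ids)


def changed_reactions(
    v0,
    v1,
    tol: float = DEFAULT_TOL,
    *,
    reaction_ids: Sequence[str] | None = None,
    relative: bool = False,
) -> list[str]:
    """Reaction ids with ``|v1_j - v0_j| > tol``, input order preserved.

    ``v0``/``v1`` may be :class:`FluxState` objects or raw vectors (then
    ``reaction_ids`` is required).  With ``relative=True`` the tolerance is
    scaled by ``max(1, |v0_j|)``.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    a, ids_a = _as_flux_vector(v0, reaction_ids)
    b, ids_b = _as_flux_vector(v1, reaction_ids)
    if len(a) != len(b):
        raise ValueError(f"flux vectors differ in length ({len(a)} vs {len(b)})")
    if ids_a != ids_b:
        raise ValueError("flux vectors are indexed by different reaction sets")
    out = []
    for rid, x0, x1 in zip(ids_a, a, b):
        scale = max(1.0, abs(x0)) if relative else 1.0
        if abs(x1 - x0) > tol * scale:
            out.append(rid)
    return out


def build_subnetwork(
    network: MetabolicNetwork, changed: Iterable[str]
) -> MetabolicNetwork:
    """Subnetwork of the changed reactions and their reactants/products."""
    return network.restricted_to(changed)


def prune_zero_indegree(
    subnetwork: MetabolicNetwork, iterative: bool = False
) -> MetabolicNetwork:
    """Delete every compound that is a product of no subnetwork reaction.

    A single pass by default (compounds entering from outside are dropped
    once, then source reactions are read off); ``iterative=True`` repeats to
    a fixed point, which can further strip compounds whose only producers
    became reactant-free — a stricter variant, not the default.
    """
    mets = list(subnetwork.metabolites)
    rxns = list(subnetwork.reactions)
    while True:
        produced = {m for r in rxns for m in r.products}
        drop = {m.id for m in mets if m.id not in produced}
        if not drop:
            break
        mets = [m for m in mets if m.id not in drop]
        new_rxns = []
        for r in rxns:
            reactants = {m: c for m, c in r.reactants.items() if m not in drop}
            if reactants != r.reactants:
                r = Reaction(r.id, reactants, r.products, r.enzymes)
            new_rxns.append(r)
        rxns = new_rxns
        if not iterative:
            break
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return MetabolicNetwork(mets, rxns, dict(subnetwork.flux_upper_hints))


def identify_targets(
    pathologic: FluxState,
    medication: MedicationSolution,
    network: MetabolicNetwork,
    tol: float = DEFAULT_TOL,
    *,
    iterative_prune: bool = False,
    relative: bool = False,
) -> TargetReport:
    """Full contrast-and-prune pipeline; returns a :class:`TargetReport`."""
    med_state = medication.state
    changed_ids = changed_reactions(pathologic, med_state, tol, relative=relative)
    sub = build_subnetwork(network, changed_ids)
    pruned = prune_zero_indegree(sub, iterative=iterative_prune)
    v0 = dict(zip(pathologic.reaction_ids, pathologic.v))
    v1 = dict(zip(med_state.reaction_ids, med_state.v))
    changed = tuple(ChangedReaction(rid, v0[rid], v1[rid]) for rid in changed_ids)
    unchanged = set(pathologic.reaction_ids) - set(changed_ids)
    enzymes_of_unchanged = {
        e for r in network.reactions if r.id in unchanged for e in r.enzymes
    }
    targets = []
    for r in pruned.reactions:
        if r.reactants:
            continue
        full = network.reaction(r.id)
        targets.append(
            Target(
                reaction_id=r.id,
                enzymes=full.enzymes,
                v0=v0[r.id],
                v1=v1[r.id],
                shared_enzymes=tuple(e for e in full.enzymes if e in enzymes_of_unchanged),
            )
        )
    return TargetReport(
        changed=changed,
        subnetwork=pruned,
        targets=tuple(targets),
        side_effect=medication.side_effect,
    )


def verify_targets(
    network: MetabolicNetwork,
    config: ScenarioConfig,
    ranges: HealthyRanges,
    targets: Iterable[Target] | Mapping[str, float],
    *,
    tie_break: str | None = "max_total_flux",
) -> MedicationSolution:
    """Confirm that pinning only the target fluxes reaches the cure.

    Re-solves the *pathologic* model with each target reaction's flux fixed
    at its required medication value and evaluates the resulting mass flows
    against the healthy ranges.  The returned :class:`MedicationSolution`
    carries the implied deviations and side effect; an infeasible fixed-flux
    model (status carried on ``.state``) is a verification failure.
    """
    if isinstance(targets, Mapping):
        fixed = {rid: float(v) for rid, v in targets.items()}
    else:
        fixed = {t.reaction_id: t.v1 for t in targets}
    state = solve_pathologic(network, config, fixed_fluxes=fixed, tie_break=tie_break)
    if not state.ok:
        return MedicationSolution(state=state, dev_above={}, dev_below={}, side_effect=float("nan"))
    dev_above: dict[str, float] = {}
    dev_below: dict[str, float] = {}
    side_effect = 0.0
    known = set(state.metabolite_ids)
    for mid in ranges.non_disease:
        if mid not in known:
            continue
        dplus, dminus = ranges.deviation(mid, state.mass_flow(mid))
        dev_above[mid] = dplus
        dev_below[mid] = dminus
        side_effect += ranges.weight(mid) * (dplus + dminus)
    for mid in ranges.disease:
        if mid not in known:
            continue
        a, b = ranges.ranges[mid]
        xval = state.mass_flow(mid)
        if not (a - DEFAULT_TOL <= xval <= b + DEFAULT_TOL):
            warnings.warn(
                f"verification: disease compound {mid} at {xval:.6g} is outside "
                f"its healthy range [{a}, {b}] under the fixed target fluxes",
                stacklevel=2,
            )
    return MedicationSolution(
        state=state, dev_above=dev_above, dev_below=dev_below, side_effect=side_effect
    )
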