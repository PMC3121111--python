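"""Model/Results front end for the two-stage drug-target analysis.

:class:`TwoStageFBA` bundles a network and a scenario the way a statistical
model bundles data and design; ``fit()`` runs the pathologic solve, the
medication solve and the target identification and returns a
:class:`TwoStageFBAResults` carrying both states, the target report, the
optional verification, and a ``summary()`` table.

    >>> from fluxtarget import TwoStageFBA, toy_network
    >>> network, config, ranges, _ = toy_network()
    >>> res = TwoStageFBA(network, config, ranges).fit()
    >>> round(res.side_effect, 3)
    3.667
    >>> res.target_ids
    ('R2', 'R3', 'R4')
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .medication import TIE_BREAK_MIN_CHANGE, MedicationSolution, solve_medication
from .network import MetabolicNetwork
from .pathologic import (
    TIE_BREAK_MAX_FLUX,
    FluxState,
    apply_disease_knockouts,
    solve_pathologic,
)
from .scenario import HealthyRanges, ScenarioConfig
from .targets import DEFAULT_TOL, TargetReport, identify_targets, verify_targets

__all__ = ["TwoStageFBA", "TwoStageFBAResults"]


class TwoStageFBA:
    """Two-stage FBA drug-target model for one network + scenario."""

    def __init__(
        self,
        network: MetabolicNetwork,
        config: ScenarioConfig,
        ranges: HealthyRanges,
    ) -> None:
        self.network = network
        self.config = config
        self.ranges = ranges

    @classmethod
    def from_files(cls, network_path, scenario_path) -> "TwoStageFBA":
        """Build from a network TSV and a scenario YAML/JSON file."""
        from .io import read_network, read_scenario

        network = read_network(network_path)
        config, ranges = read_scenario(scenario_path)
        return cls(network, config, ranges)

    def fit(
        self,
        *,
        tol: float = DEFAULT_TOL,
        pathologic_tie_break: str | None = TIE_BREAK_MAX_FLUX,
        medication_tie_break: str | None = TIE_BREAK_MIN_CHANGE,
        iterative_prune: bool = False,
        maximize_biomass: bool = False,
        verify: bool = True,
    ) -> "TwoStageFBAResults":
        working = apply_disease_knockouts(self.network, self.config)
        pathologic = solve_pathologic(
            working, self.config, tie_break=pathologic_tie_break, apply_knockouts=False
        )
        if not pathologic.ok:
            raise RuntimeError(f"pathologic LP is {pathologic.status}")
        medication = solve_medication(
            working,
            self.config,
            self.ranges,
            reference=pathologic,
            tie_break=medication_tie_break,
            maximize_biomass=maximize_biomass,
            apply_knockouts=False,
        )
        if not medication.ok:
            raise RuntimeError(f"medication LP is {medication.status}")
        report = identify_targets(
            pathologic, medication, working, tol, iterative_prune=iterative_prune
        )
        verification = None
        if verify and report.targets:
            verification = verify_targets(
                working, self.config, self.ranges, report.targets
            )
        return TwoStageFBAResults(
            model=self,
            pathologic=pathologic,
            medication=medication,
            report=report,
            verification=verification,
        )


@dataclass
class TwoStageFBAResults:
    """Fitted two-stage analysis: both states, targets, verification."""

    model: TwoStageFBA
    pathologic: FluxState
    medication: MedicationSolution
    report: TargetReport
    verification: MedicationSolution | None = None

    @property
    def side_effect(self) -> float:
        return self.medication.side_effect

    @property
    def target_ids(self) -> tuple[str, ...]:
        return self.report.target_ids

    def flux_frame(self) -> pd.DataFrame:
        """Per-reaction v0, v1, delta, changed/target flags and enzymes."""
        changed = set(self.report.changed_ids)
        tgt = set(self.target_ids)
        med = dict(zip(self.medication.state.reaction_ids, self.medication.state.v))
        rows = []
        for rid, v0 in zip(self.pathologic.reaction_ids, self.pathologic.v):
            v1 = med[rid]
            rxn = next(r for r in self.model.network.reactions if r.id == rid)
            rows.append(
                (rid, v0, v1, v1 - v0, rid in changed, rid in tgt, ",".join(rxn.enzymes))
            )
        return pd.DataFrame(
            rows,
            columns=["reaction_id", "v0", "v1", "delta", "changed", "target", "enzymes"],
        )

    def mass_flow_frame(self) -> pd.DataFrame:
        """Per-metabolite x0, x1, healthy range and medication deviation."""
        ranges = self.model.ranges
        med = dict(zip(self.medication.state.metabolite_ids, self.medication.state.x))
        rows = []
        for mid, x0 in zip(self.pathologic.metabolite_ids, self.pathologic.x):
            x1 = med[mid]
            a, b = ranges.ranges.get(mid, (0.0, float("inf")))
            dev = self.medication.dev_above.get(mid, 0.0) + self.medication.dev_below.get(mid, 0.0)
            rows.append((mid, x0, x1, a, b, mid in ranges.disease, dev))
        return pd.DataFrame(
            rows,
            columns=["metabolite_id", "x0", "x1", "range_low", "range_high", "disease", "deviation"],
        )

    def summary(self) -> str:
        """Human-readable fit summary in the style of a model results table."""
        lines = [
            "Two-stage FBA drug-target analysis",
            "=" * 54,
            f"Metabolites: {self.pathologic.metabolite_ids.__len__():>4}    "
            f"Reactions: {self.pathologic.reaction_ids.__len__():>4}",
            f"Pathologic objective (weighted mass flow): {self.pathologic.objective:.6g}",
            f"Side effect (medication optimum):          {self.side_effect:.6g}",
            f"Changed reactions: {len(self.report.changed)}    Targets: {len(self.report.targets)}",
            "-" * 54,
            "Targets (dose proxy = required flux change):",
        ]
        for t in self.report.targets:
            enz = ",".join(t.enzymes) or "-"
            lines.append(
                f"  {t.reaction_id:<8} {enz:<16} v0={t.v0:8.4g}  v1={t.v1:8.4g} "
                f"Δv={t.delta:8.4g}  [{t.mode}]"
            )
        if not self.report.targets:
            lines.append("  (none — medication leaves all fluxes unchanged)")
        if self.verification is not None:
            ok = self.verification.ok
            lines.append("-" * 54)
            lines.append(
                "Verification (targets pinned, pathologic re-solve): "
                + (f"side effect {self.verification.side_effect:.6g}" if ok else "INFEASIBLE")
            )
        return "\n".join(lines)
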