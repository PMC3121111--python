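"""Scenario configuration: objective weights, capacity bounds, knockouts,
and healthy mass-flow ranges.

A *scenario* is everything about a study that is not network topology: which
metabolites carry objective weight (biomass precursors), the flux capacity
``U_j`` of each reaction, optional mass-flow caps ``q_i``, enzymes inhibited
in the disease state, and — for the medication stage — the healthy range
``[a_i, b_i]`` of each clinically ranged metabolite together with the
disease-causing set ``P``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = ["ScenarioConfig", "HealthyRanges", "ConfigurationError"]

INF = float("inf")


class ConfigurationError(ValueError):
    """Raised for invalid or inconsistent scenario configuration."""


@dataclass(frozen=True)
class ScenarioConfig:
    """Stage-1 (pathologic) scenario parameters.

    Parameters
    ----------
    objective_weights : map metabolite-id -> nonnegative weight
        The ``w_i`` of the pathologic objective ``max sum_i w_i x_i``;
        typically 1 on biomass precursors and 0 elsewhere.  At least one
        weight must be nonzero.
    flux_upper : map reaction-id -> U_j
        Per-reaction flux capacity overrides (flux units).
    default_flux_upper : float
        ``U_j`` for reactions with no override (may be ``inf``).
    massflow_upper : map metabolite-id -> q_i
        Mass-flow caps; metabolites not listed default to
        ``default_massflow_upper`` (``inf`` by default, matching the usual
        practice of bounding fluxes only).
    inhibited_enzymes : enzymes knocked out in the disease state; every
        reaction they catalyze is removed before the pathologic solve.
    """

    objective_weights: Mapping[str, float]
    flux_upper: Mapping[str, float] = field(default_factory=dict)
    default_flux_upper: float = INF
    massflow_upper: Mapping[str, float] = field(default_factory=dict)
    default_massflow_upper: float = INF
    inhibited_enzymes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "objective_weights", dict(self.objective_weights))
        object.__setattr__(self, "flux_upper", dict(self.flux_upper))
        object.__setattr__(self, "massflow_upper", dict(self.massflow_upper))
        object.__setattr__(self, "inhibited_enzymes", tuple(self.inhibited_enzymes))
        for met, w in self.objective_weights.items():
            if w < 0 or math.isnan(w):
                raise ConfigurationError(f"objective weight for {met!r} must be >= 0, got {w}")
        if not any(w > 0 for w in self.objective_weights.values()):
            raise ConfigurationError("objective_weights must be nonzero for at least one metabolite")
        for rid, u in {**self.flux_upper, "<default>": self.default_flux_upper}.items():
            if u < 0 or math.isnan(u):
                raise ConfigurationError(f"flux upper bound for {rid!r} must be >= 0, got {u}")
        for mid, q in {**self.massflow_upper, "<default>": self.default_massflow_upper}.items():
            if q <= 0 or math.isnan(q):
                raise ConfigurationError(
                    f"mass-flow upper bound for {mid!r} must be > 0 (or inf), got {q}"
                )

    def flux_bound(self, reaction_id: str, hint: float | None = None) -> float:
        """Resolve ``U_j``: explicit override > network-file hint > default."""
        if reaction_id in self.flux_upper:
            return float(self.flux_upper[reaction_id])
        if hint is not None:
            return float(hint)
        return float(self.default_flux_upper)

    def massflow_bound(self, metabolite_id: str) -> float:
        return float(self.massflow_upper.get(metabolite_id, self.default_massflow_upper))


@dataclass(frozen=True)
class HealthyRanges:
    """Healthy mass-flow ranges and the disease-causing compound set.

    ``ranges`` maps metabolite id to ``(a_i, b_i)`` with
    ``0 <= a_i <= b_i <= inf``.  ``disease`` is the set ``P`` of
    disease-causing compounds, whose ranges are enforced as hard constraints
    in the medication LP.  Every other ranged metabolite belongs to the
    non-disease set ``N`` and contributes its (weighted) range deviation to
    the side effect; metabolites without a range entry contribute nothing
    (equivalent to the range ``[0, inf)``).
    """

    ranges: Mapping[str, tuple[float, float]]
    disease: tuple[str, ...]
    side_effect_weights: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ranges = {}
        for met, pair in dict(self.ranges).items():
            a, b = (float(pair[0]), float(pair[1]))
            if math.isnan(a) or math.isnan(b) or a < 0 or a > b:
                raise ConfigurationError(
                    f"healthy range for {met!r} must satisfy 0 <= a <= b, got ({a}, {b})"
                )
            ranges[met] = (a, b)
        object.__setattr__(self, "ranges", ranges)
        object.__setattr__(self, "disease", tuple(self.disease))
        object.__setattr__(self, "side_effect_weights", dict(self.side_effect_weights))
        missing = [p for p in self.disease if p not in ranges]
        if missing:
            raise ConfigurationError(
                f"disease compounds without a healthy range entry: {missing}"
            )
        for met, w in self.side_effect_weights.items():
            if w < 0 or math.isnan(w):
                raise ConfigurationError(
                    f"side-effect weight for {met!r} must be >= 0, got {w}"
                )

    @property
    def non_disease(self) -> tuple[str, ...]:
        """The set N: every ranged metabolite that is not disease-causing."""
        P = set(self.disease)
        return tuple(m for m in self.ranges if m not in P)

    def weight(self, metabolite_id: str) -> float:
        return float(self.side_effect_weights.get(metabolite_id, 1.0))

    def deviation(self, metabolite_id: str, x: float) -> tuple[float, float]:
        """Closed-form deviations ``(d+, d-) = (max(0, x-b), max(0, a-x))``."""
        a, b = self.ranges.get(metabolite_id, (0.0, INF))
        return (max(0.0, x - b), max(0.0, a - x))
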