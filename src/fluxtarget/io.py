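"""File formats: network TSV, scenario YAML/JSON, result reports.

Network file
------------
UTF-8 TSV with header ``reaction_id  equation  enzymes  flux_upper``; one
row per reaction, ``#`` lines ignored.  ``equation`` uses the reaction
grammar of :mod:`fluxtarget.network` (``2 C1 + C2 -> C5 + C6``; ``<->`` for
reversible, split on read).  ``enzymes`` is a comma-separated list (may be
empty), ``flux_upper`` a number, ``inf``, or empty (defer to the
scenario's flux bounds; an explicit ``inf`` wins over the scenario default).  The metabolite list is inferred
from the equations (first-mention order) unless a sidecar TSV
``metabolite_id  name`` is supplied or the file carries a
``#! metabolites: id,id,...`` directive line (which :func:`write_network`
emits so that round-trips preserve the declared ordering).

Scenario file
-------------
YAML (JSON works too) with the keys ``objective_weights``,
``default_flux_upper``, ``flux_upper``, ``massflow_upper``,
``inhibited_enzymes``, ``healthy_ranges`` (map id -> [a, b], ``inf``
allowed), ``disease_compounds``, ``side_effect_weights``, ``tolerances``,
``tie_break``.  Unknown keys are rejected.

Reports are written deterministically (fixed ordering, 6 significant
digits, ``inf`` literal), with byte-identical TSV and field-identical JSON.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Mapping

import yaml

from .medication import MedicationSolution
from .network import (
    MetabolicNetwork,
    Metabolite,
    format_reaction_equation,
    parse_reaction_equation,
    split_reversible,
)
from .pathologic import FluxState
from .scenario import ConfigurationError, HealthyRanges, ScenarioConfig
from .targets import TargetReport

__all__ = [
    "read_network",
    "write_network",
    "read_scenario",
    "write_scenario",
    "write_report",
    "NetworkFileError",
]

INF = float("inf")


class NetworkFileError(ValueError):
    """Raised for malformed network files (message carries the row number)."""


def _parse_float(text: str, where: str) -> float:
    text = text.strip().lower()
    if text in ("inf", "+inf", "infinity"):
        return INF
    try:
        return float(text)
    except ValueError as exc:
        raise NetworkFileError(f"{where}: cannot parse number {text!r}") from exc


def read_network(path, metabolites_path=None) -> MetabolicNetwork:
    """Read a network TSV; returns a finalized (reversible-split) network."""
    path = Path(path)
    rows = []
    header: list[str] | None = None
    directive_order: list[str] | None = None
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        line = raw.rstrip("\n")
        if line.lstrip().startswith("#!"):
            body = line.lstrip()[2:].strip()
            if body.startswith("metabolites:"):
                directive_order = [
                    m.strip() for m in body.split(":", 1)[1].split(",") if m.strip()
                ]
            continue
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = [f.strip() for f in fields]
            expected = ["reaction_id", "equation", "enzymes", "flux_upper"]
            if header != expected:
                raise NetworkFileError(
                    f"{path}:{lineno}: header must be {expected}, got {header}"
                )
            continue
        if len(fields) != 4:
            raise NetworkFileError(
                f"{path}:{lineno}: expected 4 tab-separated fields, got {len(fields)}"
            )
        rows.append((lineno, [f.strip() for f in fields]))
    if header is None:
        raise NetworkFileError(f"{path}: empty network file")

    reactions = []
    hints: dict[str, float] = {}
    seen: dict[str, int] = {}
    for lineno, (rid, equation, enzymes, upper) in rows:
        if rid in seen:
            raise NetworkFileError(
                f"{path}:{lineno}: duplicate reaction_id {rid!r} "
                f"(first defined at row {seen[rid]})"
            )
        seen[rid] = lineno
        enzyme_list = tuple(e.strip() for e in enzymes.split(",") if e.strip())
        try:
            rxn = parse_reaction_equation(equation, rid, enzyme_list)
        except ValueError as exc:
            raise NetworkFileError(f"{path}:{lineno}: {exc}") from exc
        reactions.append(rxn)
        if upper:
            hints[rid] = _parse_float(upper, f"{path}:{lineno} flux_upper")

    finalized = split_reversible(reactions)
    for r in finalized:
        parent = r.id.rsplit("_", 1)[0]
        if r.id not in hints and parent in hints:
            hints[r.id] = hints[parent]  # _fwd/_bwd copies inherit the bound

    if metabolites_path is not None:
        mets = _read_metabolite_sidecar(metabolites_path)
    elif directive_order is not None:
        mets = [Metabolite(mid) for mid in directive_order]
    else:
        order: list[str] = []
        for r in finalized:
            for mid in list(r.reactants) + list(r.products):
                if mid not in order:
                    order.append(mid)
        mets = [Metabolite(mid) for mid in order]
    return MetabolicNetwork(
        mets, finalized, {r.id: hints[r.id] for r in finalized if r.id in hints}
    )


def _read_metabolite_sidecar(path) -> list[Metabolite]:
    mets = []
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), start=1):
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        fields = raw.split("\t")
        if fields[0].strip() == "metabolite_id":
            continue
        name = fields[1].strip() if len(fields) > 1 else ""
        mets.append(Metabolite(fields[0].strip(), name))
    return mets


def _fmt(value: float) -> str:
    if math.isinf(value):
        return "inf"
    return format(value, ".6g")


def write_network(network: MetabolicNetwork, path) -> None:
    lines = [
        f"#! metabolites: {','.join(network.metabolite_ids)}",
        "reaction_id\tequation\tenzymes\tflux_upper",
    ]
    for r in network.reactions:
        upper = network.flux_upper_hints.get(r.id)
        lines.append(
            f"{r.id}\t{format_reaction_equation(r)}\t{','.join(r.enzymes)}\t"
            + (_fmt(upper) if upper is not None else "")
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


_SCENARIO_KEYS = {
    "objective_weights",
    "default_flux_upper",
    "flux_upper",
    "massflow_upper",
    "inhibited_enzymes",
    "healthy_ranges",
    "disease_compounds",
    "side_effect_weights",
    "tolerances",
    "tie_break",
}


def _num(value) -> float:
    if isinstance(value, str):
        return _parse_float(value, "scenario")
    return float(value)


def read_scenario(path) -> tuple[ScenarioConfig, HealthyRanges]:
    """Read a scenario YAML/JSON file; returns ``(config, ranges)``."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: scenario file must contain a mapping")
    unknown = sorted(set(raw) - _SCENARIO_KEYS)
    if unknown:
        raise ConfigurationError(
            f"{path}: unknown scenario keys {unknown}; allowed: {sorted(_SCENARIO_KEYS)}"
        )
    config = ScenarioConfig(
        objective_weights={k: _num(v) for k, v in (raw.get("objective_weights") or {}).items()},
        flux_upper={k: _num(v) for k, v in (raw.get("flux_upper") or {}).items()},
        default_flux_upper=_num(raw.get("default_flux_upper", INF)),
        massflow_upper={k: _num(v) for k, v in (raw.get("massflow_upper") or {}).items()},
        inhibited_enzymes=tuple(raw.get("inhibited_enzymes") or ()),
    )
    ranges_raw = raw.get("healthy_ranges") or {}
    ranges = HealthyRanges(
        ranges={
            k: (_num(v[0]), _num(v[1])) for k, v in ranges_raw.items()
        },
        disease=tuple(raw.get("disease_compounds") or ()),
        side_effect_weights={
            k: _num(v) for k, v in (raw.get("side_effect_weights") or {}).items()
        },
    )
    return config, ranges


def write_scenario(config: ScenarioConfig, ranges: HealthyRanges, path) -> None:
    doc = {
        "objective_weights": {k: float(v) for k, v in config.objective_weights.items()},
        "default_flux_upper": "inf"
        if math.isinf(config.default_flux_upper)
        else float(config.default_flux_upper),
        "flux_upper": {k: float(v) for k, v in config.flux_upper.items()},
        "massflow_upper": {k: float(v) for k, v in config.massflow_upper.items()},
        "inhibited_enzymes": list(config.inhibited_enzymes),
        "healthy_ranges": {
            k: ["inf" if math.isinf(b) else float(b) for b in pair]
            for k, pair in ranges.ranges.items()
        },
        "disease_compounds": list(ranges.disease),
        "side_effect_weights": {k: float(v) for k, v in ranges.side_effect_weights.items()},
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


def _report_dict(
    report: TargetReport,
    pathologic: FluxState,
    medication: MedicationSolution,
    ranges: HealthyRanges | None = None,
) -> dict:
    changed = set(report.changed_ids)
    tgt = set(report.target_ids)
    med = dict(zip(medication.state.reaction_ids, medication.state.v))
    reactions = []
    for rid, v0 in zip(pathologic.reaction_ids, pathologic.v):
        v1 = med.get(rid, float("nan"))
        reactions.append(
            {
                "reaction_id": rid,
                "v0": _fmt(v0),
                "v1": _fmt(v1),
                "delta": _fmt(v1 - v0),
                "changed": rid in changed,
                "target": rid in tgt,
            }
        )
    medx = dict(zip(medication.state.metabolite_ids, medication.state.x))
    metabolites = []
    for mid, x0 in zip(pathologic.metabolite_ids, pathologic.x):
        a, b = (ranges.ranges.get(mid, (0.0, INF)) if ranges else (0.0, INF))
        dev = medication.dev_above.get(mid, 0.0) + medication.dev_below.get(mid, 0.0)
        metabolites.append(
            {
                "metabolite_id": mid,
                "x0": _fmt(x0),
                "x1": _fmt(medx.get(mid, float("nan"))),
                "range_low": _fmt(a),
                "range_high": _fmt(b),
                "deviation": _fmt(dev),
            }
        )
    targets = [
        {
            "reaction_id": t.reaction_id,
            "enzymes": list(t.enzymes),
            "v0": _fmt(t.v0),
            "v1": _fmt(t.v1),
            "delta": _fmt(t.delta),
            "mode": t.mode,
            "shared_enzymes": list(t.shared_enzymes),
        }
        for t in report.targets
    ]
    return {
        "side_effect": _fmt(report.side_effect),
        "reactions": reactions,
        "metabolites": metabolites,
        "targets": targets,
    }


def write_report(
    report: TargetReport,
    pathologic: FluxState,
    medication: MedicationSolution,
    path,
    format: str = "tsv",
    ranges: HealthyRanges | None = None,
) -> None:
    """Write the per-reaction/per-metabolite report (``tsv`` or ``json``)."""
    doc = _report_dict(report, pathologic, medication, ranges)
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")
        return
    if format != "tsv":
        raise ValueError(f"unknown report format {format!r}")
    lines = ["# reactions", "reaction_id\tv0\tv1\tdelta\tchanged\ttarget"]
    for row in doc["reactions"]:
        lines.append(
            "\t".join(
                [
                    row["reaction_id"],
                    row["v0"],
                    row["v1"],
                    row["delta"],
                    str(int(row["changed"])),
                    str(int(row["target"])),
                ]
            )
        )
    lines += ["# metabolites", "metabolite_id\tx0\tx1\trange_low\trange_high\tdeviation"]
    for row in doc["metabolites"]:
        lines.append(
            "\t".join(
                [
                    row["metabolite_id"],
                    row["x0"],
                    row["x1"],
                    row["range_low"],
                    row["range_high"],
                    row["deviation"],
                ]
            )
        )
    lines += ["# targets", "reaction_id\tenzymes\tv0\tv1\tdelta\tmode"]
    for row in doc["targets"]:
        lines.append(
            "\t".join(
                [
                    row["reaction_id"],
                    ",".join(row["enzymes"]),
                    row["v0"],
                    row["v1"],
                    row["delta"],
                    row["mode"],
                ]
            )
        )
    lines += ["# summary", f"side_effect\t{doc['side_effect']}"]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
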