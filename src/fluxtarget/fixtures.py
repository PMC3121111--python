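"""Built-in study networks and a seeded random-network generator.

:func:`toy_network` reconstructs the 12-metabolite / 8-reaction
illustrative network used throughout the documentation and tests, together
with its biomass scenario and two sets of healthy ranges.

:func:`generate_network` draws layered, acyclic networks that are feasible
by construction — every property test needs a solvable instance, and a
layered DAG avoids the rejection storms of uniform bipartite sampling.
:func:`plant_disease_scenario` then plants a disease on a generated
network (a sink flowing too high) with a graph-derived ground-truth set of
source reactions for recall checks of the target-identification pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .network import (
    MetabolicNetwork,
    Metabolite,
    Reaction,
    build_network,
    parse_reaction_equation,
)
from .pathologic import solve_pathologic
from .scenario import HealthyRanges, ScenarioConfig

__all__ = [
    "toy_network",
    "GeneratorParams",
    "generate_network",
    "plant_disease_scenario",
]

# The illustrative network.  NOTE: the source material prints R7 as
# "C6 + 3C6 -> 2C11 + 3C12", which is inconsistent with every printed flux
# and mass-flow vector; C6 + 3 C7 -> 2 C11 + 3 C12 is the unique
# stoichiometry under which all four printed vectors balance exactly, and
# is what this fixture uses.
_TOY_EQUATIONS = [
    ("R1", "2 C1 + C2 -> C5 + C6"),
    ("R2", "4 C3 -> 3 C6 + C7"),
    ("R3", "3 C2 -> C8"),
    ("R4", "C4 -> 2 C8"),
    ("R5", "2 C5 -> 3 C9"),
    ("R6", "2 C6 -> C10 + 2 C11"),
    ("R7", "C6 + 3 C7 -> 2 C11 + 3 C12"),
    ("R8", "2 C8 -> 3 C12"),
]


def toy_network() -> tuple[MetabolicNetwork, ScenarioConfig, HealthyRanges, HealthyRanges]:
    """The illustrative 12-metabolite / 8-reaction network and scenarios.

    Returns ``(network, config, ranges_scenario1, ranges_scenario2)``:
    biomass weights 1 on {C8, C9, C11, C12}, flux caps ``U_j = 10`` for all
    reactions, no mass-flow caps.  Scenario 1 ranges: C9, C10, C11 in
    [10, 15] and C12 in [0, 1] with disease set {C11, C12} (in the
    pathologic state C11 flows at 22.5 and C12 at 33.75, both far out of
    range).  Scenario 2 relaxes the ranges to C9, C12 in [10, 15], C10 in
    [5, 15], C11 in [15, 20] — wide enough for a side-effect-free cure.
    """
    reactions = [
        parse_reaction_equation(eq, rid, enzymes=(f"E{rid[1:]}",))
        for rid, eq in _TOY_EQUATIONS
    ]
    network = build_network([f"C{i}" for i in range(1, 13)], reactions)
    config = ScenarioConfig(
        objective_weights={"C8": 1.0, "C9": 1.0, "C11": 1.0, "C12": 1.0},
        default_flux_upper=10.0,
    )
    ranges1 = HealthyRanges(
        ranges={"C9": (10, 15), "C10": (10, 15), "C11": (10, 15), "C12": (0, 1)},
        disease=("C11", "C12"),
    )
    ranges2 = HealthyRanges(
        ranges={"C9": (10, 15), "C12": (10, 15), "C10": (5, 15), "C11": (15, 20)},
        disease=("C11", "C12"),
    )
    return network, config, ranges1, ranges2


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of the layered random-network generator.

    ``n_layers`` metabolite layers with reactions always pointing from an
    earlier layer to a later one guarantee a directed acyclic structure, so
    a feasible nonzero flux state exists (verified internally by solving
    the pathologic LP with uniform sink weights).
    """

    n_metabolites: int = 12
    n_reactions: int = 8
    n_layers: int = 3
    max_coefficient: int = 3
    flux_upper: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_layers < 2:
            raise ValueError("n_layers must be >= 2")
        if self.n_metabolites < self.n_layers:
            raise ValueError("need at least one metabolite per layer")
        if self.n_reactions < 1 or self.max_coefficient < 1 or self.flux_upper <= 0:
            raise ValueError("invalid generator parameters")


def _draw_network(params: GeneratorParams, rng: np.random.Generator) -> MetabolicNetwork:
    mids = [f"M{i+1}" for i in range(params.n_metabolites)]
    # near-even layer assignment, every layer nonempty
    layer_of = {}
    base = params.n_metabolites // params.n_layers
    extra = params.n_metabolites % params.n_layers
    pos = 0
    for layer in range(params.n_layers):
        size = base + (1 if layer < extra else 0)
        for mid in mids[pos : pos + size]:
            layer_of[mid] = layer
        pos += size
    reactions = []
    for j in range(params.n_reactions):
        split = int(rng.integers(1, params.n_layers))  # reactants < split <= products
        lower = [m for m in mids if layer_of[m] < split]
        upper = [m for m in mids if layer_of[m] >= split]
        n_react = int(rng.integers(1, min(3, len(lower)) + 1))
        n_prod = int(rng.integers(1, min(3, len(upper)) + 1))
        reactants = rng.choice(lower, size=n_react, replace=False)
        products = rng.choice(upper, size=n_prod, replace=False)
        coef = lambda: int(rng.integers(1, params.max_coefficient + 1))
        reactions.append(
            Reaction(
                f"R{j+1}",
                {m: coef() for m in reactants},
                {m: coef() for m in products},
                enzymes=(f"E{j+1}",),
            )
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # isolated metabolites are acceptable here
        return MetabolicNetwork([Metabolite(m) for m in mids], reactions)


def _uniform_sink_config(network: MetabolicNetwork, flux_upper: float) -> ScenarioConfig:
    sinks = network.metabolites_with_role("produced_only")
    weights = {m: 1.0 for m in (sinks or network.metabolite_ids)}
    return ScenarioConfig(objective_weights=weights, default_flux_upper=flux_upper)


def generate_network(params: GeneratorParams, max_retries: int = 25) -> MetabolicNetwork:
    """Seeded, reproducible random layered network with a nonzero feasible
    flux state (resamples up to ``max_retries`` times, then raises)."""
    rng = np.random.default_rng(params.seed)
    for _ in range(max_retries):
        network = _draw_network(params, rng)
        if not network.metabolites_with_role("produced_only"):
            continue
        config = _uniform_sink_config(network, params.flux_upper)
        state = solve_pathologic(network, config, tie_break=None)
        if state.ok and state.objective > 1e-9:
            return network
    raise RuntimeError(
        f"could not draw a feasible network in {max_retries} attempts "
        f"(params: {params})"
    )


def _source_reactions_upstream_of(network: MetabolicNetwork, target_met: str) -> set[str]:
    """Source reactions (no produced reactant) from which ``target_met`` is
    reachable over the bipartite reaction->product->reaction edges."""
    produced = {m for r in network.reactions for m in r.products}
    consumers: dict[str, list[Reaction]] = {}
    for r in network.reactions:
        for m in r.reactants:
            consumers.setdefault(m, []).append(r)

    def reaches(rxn: Reaction) -> bool:
        seen = set()
        stack = [rxn]
        while stack:
            r = stack.pop()
            if r.id in seen:
                continue
            seen.add(r.id)
            if target_met in r.products:
                return True
            for m in r.products:
                stack.extend(consumers.get(m, []))
        return False

    sources = [r for r in network.reactions if not (set(r.reactants) & produced)]
    return {r.id for r in sources if reaches(r)}


def plant_disease_scenario(
    network: MetabolicNetwork, seed: int = 0, flux_upper: float = 10.0
) -> tuple[ScenarioConfig, HealthyRanges, set[str]]:
    """Plant a disease on a generated network.

    Solves the pathologic LP with uniform sink weights, picks a sink with
    nonzero mass flow as the disease compound, sets its healthy range to
    half its pathologic flow (so medication must reroute flux) and wide
    ranges ``[0, pathologic flow]`` on the other sinks.  Returns
    ``(config, ranges, ground_truth)`` where ``ground_truth`` is the set of
    source reactions upstream of the disease compound — the superset from
    which identified targets are expected to come.
    """
    rng = np.random.default_rng(seed)
    config = _uniform_sink_config(network, flux_upper)
    state = solve_pathologic(network, config)
    if not state.ok:
        raise RuntimeError("pathologic LP on the generated network failed")
    sinks = network.metabolites_with_role("produced_only")
    flowing = [m for m in sinks if state.mass_flow(m) > 1e-6]
    if not flowing:
        raise RuntimeError("no sink metabolite with nonzero mass flow")
    disease = flowing[int(rng.integers(0, len(flowing)))]
    ranges = {disease: (0.0, 0.5 * state.mass_flow(disease))}
    for m in flowing:
        if m != disease:
            ranges[m] = (0.0, state.mass_flow(m))
    hr = HealthyRanges(ranges=ranges, disease=(disease,))
    return config, hr, _source_reactions_upstream_of(network, disease)
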