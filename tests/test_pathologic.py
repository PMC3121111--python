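"""Stage-1 LP: construction, knockouts, optimal states, invariants."""

import numpy as np
import pytest

from fluxtarget import (
    ScenarioConfig,
    apply_disease_knockouts,
    build_network,
    build_pathologic_lp,
    check_flux_state,
    parse_reaction_equation,
    solve_pathologic,
)


def _chain(*equations, enzymes=None):
    rxns = [
        parse_reaction_equation(eq, f"R{i+1}", enzymes=(enzymes or {}).get(f"R{i+1}", ()))
        for i, eq in enumerate(equations)
    ]
    mets = []
    for r in rxns:
        for m in list(r.reactants) + list(r.products):
            if m not in mets:
                mets.append(m)
    return build_network(mets, rxns)


class TestKnockouts:
    def test_no_inhibition_is_identity(self, toy):
        network, config, *_ = toy
        assert apply_disease_knockouts(network, config) is network

    def test_inhibiting_r5_enzyme_isolates_c9(self, toy):
        network, _, *_ = toy
        config = ScenarioConfig(
            objective_weights={"C8": 1.0}, inhibited_enzymes=("E5",)
        )
        knocked = apply_disease_knockouts(network, config)
        assert knocked.n == 7 and "R5" not in knocked.reaction_ids
        assert knocked.roles["C9"] == "isolated"

    def test_enzyme_catalyzing_two_reactions_removes_both(self):
        net = _chain("A -> B", "B -> C", "B -> D", enzymes={"R2": ("E",), "R3": ("E",)})
        config = ScenarioConfig(objective_weights={"C": 1.0}, inhibited_enzymes=("E",))
        assert apply_disease_knockouts(net, config).reaction_ids == ["R1"]

    def test_unmatched_enzyme_warns_not_errors(self, toy):
        network, _, *_ = toy
        config = ScenarioConfig(
            objective_weights={"C8": 1.0}, inhibited_enzymes=("NOT_AN_ENZYME",)
        )
        with pytest.warns(UserWarning, match="NOT_AN_ENZYME"):
            out = apply_disease_knockouts(network, config)
        assert out.n == network.n


class TestLPConstruction:
    def test_toy_variable_count(self, toy):
        network, config, *_ = toy
        lp = build_pathologic_lp(network, config)
        names = lp.variable_names
        assert sum(n.startswith("v[") for n in names) == 8
        assert sum(n.startswith("x[") for n in names) == 12

    def test_c6_has_both_definitions(self, toy):
        """x_C6 = v1 + 3 v2 (production) and x_C6 = 2 v6 + v7 (consumption)."""
        network, config, *_ = toy
        lp = build_pathologic_lp(network, config)
        rows = {name: coeffs for name, coeffs, lo, hi in lp._rows}
        assert rows["produce[C6]"] == {"x[C6]": -1.0, "v[R1]": 1.0, "v[R2]": 3.0}
        assert rows["consume[C6]"] == {"x[C6]": -1.0, "v[R6]": 2.0, "v[R7]": 1.0}
        assert "balance[C6]" in rows

    def test_single_reaction_forces_equal_flows(self):
        net = _chain("A -> B")
        config = ScenarioConfig(objective_weights={"B": 1.0}, default_flux_upper=7.0)
        state = solve_pathologic(net, config)
        assert state.flux("R1") == pytest.approx(7.0)
        assert state.mass_flow("A") == pytest.approx(7.0)
        assert state.mass_flow("B") == pytest.approx(7.0)


class TestToySolution:
    """The coordinates that are unique at the optimum of the toy network."""

    def test_unique_fluxes(self, toy_pathologic):
        assert toy_pathologic.ok
        assert toy_pathologic.flux("R2") == pytest.approx(3.75, abs=1e-6)
        assert toy_pathologic.flux("R6") == pytest.approx(10.0, abs=1e-6)
        assert toy_pathologic.flux("R7") == pytest.approx(1.25, abs=1e-6)
        assert toy_pathologic.flux("R1") == pytest.approx(10.0, abs=1e-6)

    def test_degenerate_split_satisfies_aggregate(self, toy_pathologic):
        # R3/R4 individually non-unique; their C8-weighted sum is pinned
        assert toy_pathologic.flux("R3") + 2 * toy_pathologic.flux("R4") == pytest.approx(20.0, abs=1e-6)

    def test_unique_mass_flows(self, toy_pathologic):
        for mid, expected in {
            "C6": 21.25, "C9": 15.0, "C10": 10.0, "C11": 22.5, "C12": 33.75
        }.items():
            assert toy_pathologic.mass_flow(mid) == pytest.approx(expected, abs=1e-6)

    def test_objective_value(self, toy_pathologic):
        # sum of biomass mass flows: 20 + 15 + 22.5 + 33.75
        assert toy_pathologic.objective == pytest.approx(91.25, abs=1e-6)

    def test_independent_feasibility_audit(self, toy, toy_pathologic):
        network, config, *_ = toy
        assert check_flux_state(network, config, toy_pathologic) == []


class TestInvariants:
    def test_raising_capacity_never_decreases_objective(self, toy):
        network, config, *_ = toy
        base = solve_pathologic(network, config).objective
        for rid in network.reaction_ids:
            cfg = ScenarioConfig(
                objective_weights=config.objective_weights,
                default_flux_upper=10.0,
                flux_upper={rid: 20.0},
            )
            assert solve_pathologic(network, cfg).objective >= base - 1e-9

    @pytest.mark.parametrize("lam", [0.25, 2.0, 7.5])
    def test_objective_scales_with_capacities(self, toy, lam):
        network, config, *_ = toy
        base = solve_pathologic(network, config).objective
        scaled = ScenarioConfig(
            objective_weights=config.objective_weights,
            default_flux_upper=10.0 * lam,
        )
        assert solve_pathologic(network, scaled).objective == pytest.approx(lam * base)

    def test_brute_force_oracle_never_beats_lp(self):
        """Random feasible-point sampling on a 3-reaction network stays below
        the LP optimum; the LP optimum is approached within grid resolution."""
        net = _chain("2 A -> B", "B -> C", "3 B -> 2 D")
        config = ScenarioConfig(
            objective_weights={"C": 1.0, "D": 1.0}, default_flux_upper=5.0
        )
        state = solve_pathologic(net, config)
        rng = np.random.default_rng(7)
        best = -np.inf
        for _ in range(20000):
            v1 = rng.uniform(0, 5)
            v2 = rng.uniform(0, 5)
            v3 = (v1 - v2) / 3.0  # mass balance of B
            if not (0 <= v3 <= 5):
                continue
            best = max(best, v2 + (2.0 / 3.0) * (v1 - v2))
        assert best <= state.objective + 1e-6
        assert best == pytest.approx(state.objective, abs=0.05)

    def test_zero_weight_metabolites_allow_any_feasible_point(self, toy):
        network, _, *_ = toy
        config = ScenarioConfig(objective_weights={"C1": 1e-12}, default_flux_upper=10.0)
        state = solve_pathologic(network, config)
        assert state.ok
        assert check_flux_state(network, config, state) == []

    def test_unbounded_without_any_capacity(self):
        net = _chain("A -> B")
        config = ScenarioConfig(objective_weights={"B": 1.0})  # U = q = inf
        state = solve_pathologic(net, config)
        assert state.status == "unbounded"

    def test_fixed_fluxes_are_respected(self, toy):
        network, config, *_ = toy
        state = solve_pathologic(network, config, fixed_fluxes={"R2": 1.0})
        assert state.flux("R2") == pytest.approx(1.0, abs=1e-9)
        assert state.ok
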