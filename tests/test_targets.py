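"""Flux contrast, subnetwork pruning, target identification, verification."""

import numpy as np
import pytest

from fluxtarget import (
    build_network,
    build_subnetwork,
    changed_reactions,
    identify_targets,
    parse_reaction_equation,
    prune_zero_indegree,
    solve_medication,
    solve_pathologic,
    verify_targets,
)

V0_PRINTED = [10, 3.75, 10, 5, 5, 10, 1.25, 10]
V1_PRINTED = [10, 1, 0, 0, 5, 6.33, 0.33, 0]
RIDS = [f"R{i}" for i in range(1, 9)]


class TestChangedReactions:
    def test_printed_vectors(self):
        assert changed_reactions(V0_PRINTED, V1_PRINTED, reaction_ids=RIDS) == [
            "R2", "R3", "R4", "R6", "R7", "R8",
        ]

    def test_identical_vectors_give_empty_set(self):
        assert changed_reactions(V0_PRINTED, V0_PRINTED, reaction_ids=RIDS) == []

    def test_difference_exactly_at_tolerance_is_excluded(self):
        v1 = list(V0_PRINTED)
        v1[2] += 0.5
        assert changed_reactions(V0_PRINTED, v1, tol=0.5, reaction_ids=RIDS) == []
        v1[2] += 1e-9
        assert changed_reactions(V0_PRINTED, v1, tol=0.5, reaction_ids=RIDS) == ["R3"]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            changed_reactions([1.0, 2.0], [1.0], reaction_ids=["A", "B"])

    def test_accepts_flux_states(self, toy_pathologic, toy_medication):
        got = changed_reactions(toy_pathologic, toy_medication.state)
        assert got == ["R2", "R3", "R4", "R6", "R7", "R8"]


class TestSubnetwork:
    def test_toy_changed_subnetwork(self, toy):
        network, *_ = toy
        sub = build_subnetwork(network, ["R2", "R3", "R4", "R6", "R7", "R8"])
        assert sub.reaction_ids == ["R2", "R3", "R4", "R6", "R7", "R8"]
        assert sub.metabolite_ids == ["C2", "C3", "C4", "C6", "C7", "C8", "C10", "C11", "C12"]

    def test_empty_changed_set(self, toy):
        network, *_ = toy
        sub = build_subnetwork(network, [])
        assert sub.n == 0 and sub.m == 0

    def test_all_reactions_keeps_touched_metabolites(self, toy):
        network, *_ = toy
        sub = build_subnetwork(network, network.reaction_ids)
        assert sub.reaction_ids == network.reaction_ids
        assert sub.metabolite_ids == network.metabolite_ids

    def test_unknown_id_rejected(self, toy):
        network, *_ = toy
        with pytest.raises(ValueError, match="R99"):
            build_subnetwork(network, ["R99"])


class TestPruning:
    def test_toy_prune_removes_unproduced_compounds(self, toy):
        network, *_ = toy
        sub = build_subnetwork(network, ["R2", "R3", "R4", "R6", "R7", "R8"])
        pruned = prune_zero_indegree(sub)
        assert pruned.metabolite_ids == ["C6", "C7", "C8", "C10", "C11", "C12"]
        for rid in ("R2", "R3", "R4"):
            assert pruned.reaction(rid).reactants == {}
        assert pruned.reaction("R6").reactants == {"C6": 2}

    def test_fully_produced_subnetwork_unchanged(self):
        rxns = [
            parse_reaction_equation("-> A", "Rin"),
            parse_reaction_equation("A -> B", "R1"),
        ]
        net = build_network(["A", "B"], rxns)
        pruned = prune_zero_indegree(net)
        assert pruned.metabolite_ids == ["A", "B"]

    def test_chain_head_removed_once(self):
        rxns = [
            parse_reaction_equation("A -> B", "R1"),
            parse_reaction_equation("B -> C", "R2"),
        ]
        net = build_network(["A", "B", "C"], rxns)
        pruned = prune_zero_indegree(net)
        assert pruned.metabolite_ids == ["B", "C"]  # single pass: only A dropped
        iterated = prune_zero_indegree(net, iterative=True)
        assert iterated.metabolite_ids == ["B", "C"]  # B still produced by R1


class TestIdentifyTargets:
    def test_toy_scenario1_targets(self, toy, toy_pathologic, toy_medication):
        network, *_ = toy
        report = identify_targets(toy_pathologic, toy_medication, network)
        assert report.target_ids == ("R2", "R3", "R4")
        assert [t.v1 for t in report.targets] == pytest.approx([1.0, 0.0, 0.0], abs=1e-6)
        assert [t.mode for t in report.targets] == ["inhibition"] * 3
        assert report.side_effect == pytest.approx(11.0 / 3.0, abs=1e-6)
        assert set(report.target_ids) <= set(report.changed_ids)
        # every target carries its catalyzing enzyme
        assert [t.enzymes for t in report.targets] == [("E2",), ("E3",), ("E4",)]

    def test_toy_scenario2_same_targets(self, toy, toy_pathologic):
        network, config, _, ranges2 = toy
        med = solve_medication(network, config, ranges2, reference=toy_pathologic)
        report = identify_targets(toy_pathologic, med, network)
        assert report.target_ids == ("R2", "R3", "R4")
        assert report.side_effect == pytest.approx(0.0, abs=1e-6)

    def test_identical_states_give_empty_report(self, toy, toy_pathologic, toy_medication):
        network, *_ = toy
        same = toy_medication.__class__(
            state=toy_pathologic,
            dev_above={},
            dev_below={},
            side_effect=0.0,
        )
        report = identify_targets(toy_pathologic, same, network)
        assert report.changed == () and report.targets == ()
        assert report.subnetwork.n == 0

    def test_target_set_invariant_to_reaction_order(self, toy, toy_pathologic, toy_medication):
        network, config, ranges1, _ = toy
        reordered = build_network(
            network.metabolite_ids, list(reversed(network.reactions))
        )
        p = solve_pathologic(reordered, config)
        m = solve_medication(reordered, config, ranges1, reference=p)
        report = identify_targets(p, m, reordered)
        assert set(report.target_ids) == {"R2", "R3", "R4"}

    def test_pruning_never_removes_changed_products(self, toy, toy_pathologic, toy_medication):
        network, *_ = toy
        report = identify_targets(toy_pathologic, toy_medication, network)
        changed_products = {
            m for c in report.changed for m in network.reaction(c.reaction_id).products
        }
        assert changed_products <= set(report.subnetwork.metabolite_ids)


class TestVerifyTargets:
    def test_toy_scenario1_verification(self, toy, toy_pathologic, toy_medication):
        network, config, ranges1, _ = toy
        report = identify_targets(toy_pathologic, toy_medication, network)
        ver = verify_targets(network, config, ranges1, report.targets)
        assert ver.ok
        assert ver.side_effect == pytest.approx(11.0 / 3.0, abs=1e-6)
        # the fixed-target re-solve reproduces the medication state
        assert np.allclose(ver.state.v, toy_medication.state.v, atol=1e-6)

    def test_explicit_required_fluxes(self, toy):
        network, config, ranges1, _ = toy
        ver = verify_targets(network, config, ranges1, {"R2": 1.0, "R3": 0.0, "R4": 0.0})
        assert ver.side_effect == pytest.approx(11.0 / 3.0, abs=1e-6)
        for mid in ranges1.disease:
            a, b = ranges1.ranges[mid]
            assert a - 1e-6 <= ver.state.mass_flow(mid) <= b + 1e-6

    def test_fixing_nothing_reproduces_pathologic(self, toy, toy_pathologic):
        network, config, ranges1, _ = toy
        ver = verify_targets(network, config, ranges1, {})
        assert np.allclose(ver.state.v, toy_pathologic.v, atol=1e-6)

    def test_fixing_nontarget_at_pathologic_value_changes_nothing(self, toy, toy_pathologic):
        network, config, ranges1, _ = toy
        ver = verify_targets(
            network, config, ranges1, {"R1": toy_pathologic.flux("R1")}
        )
        assert np.allclose(ver.state.v, toy_pathologic.v, atol=1e-6)

    def test_infeasible_fixed_fluxes_flagged(self, toy):
        network, config, ranges1, _ = toy
        # R6 consumes 2 C6 per unit; pinning R6 above what C6 supply allows
        ver = verify_targets(
            network, config, ranges1, {"R1": 0.0, "R2": 0.0, "R6": 5.0}
        )
        assert not ver.ok
        assert np.isnan(ver.side_effect)
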