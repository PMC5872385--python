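from fractions import Fraction

import pytest

from perfcolor import (SignedGraph, enumerate_optimal, expand_coloring,
                       expand_model_set, random_signed_graph, reduce_all,
                       reduce_consistency, reduce_coregulators,
                       reduce_edge_balance)


def members_of(rg):
    return {rep: dict(sorted(sc.members.items()))
            for rep, sc in sorted(rg.subcomponents.items())}


class TestConsistencyReduction:
    def test_toy_merges_d_e_f(self, toy):
        rg = reduce_consistency(toy)
        assert members_of(rg)["D"] == {"D": 1, "E": 1, "F": 1}
        assert set(members_of(rg)) == {"A", "B", "C", "D", "G", "H", "I"}

    def test_activation_chain_collapses_to_one_subcomponent(self):
        g = SignedGraph()
        g.add_edge("a", "b", 1)
        g.add_edge("b", "c", 1)
        rg = reduce_consistency(g)
        assert members_of(rg) == {"a": {"a": 1, "b": 1, "c": 1}}

    def test_single_inhibition_gives_negative_relative_sign(self):
        g = SignedGraph()
        g.add_edge("a", "b", -1)
        rg = reduce_consistency(g)
        assert members_of(rg) == {"a": {"a": 1, "b": -1}}

    @pytest.mark.parametrize("signs,expected_c", [
        ((1, 1), 1), ((1, -1), -1), ((-1, 1), -1), ((-1, -1), 1),
    ])
    def test_relative_sign_composes_along_chain(self, signs, expected_c):
        g = SignedGraph()
        g.add_edge("a", "b", signs[0])
        g.add_edge("b", "c", signs[1])
        rg = reduce_consistency(g)
        assert rg.subcomponents["a"].members["c"] == expected_c

    def test_node_on_directed_cycle_not_merged(self):
        # forcing the cheap single-incoming edge on a conflict cycle could
        # relocate the unavoidable violation onto a heavier edge
        g = SignedGraph()
        g.add_edge("p", "t", 1, 1)
        g.add_edge("t", "q", 1, 5)
        g.add_edge("q", "p", -1, 5)
        rg = reduce_consistency(g)
        assert set(members_of(rg)) == {"p", "q", "t"}


class TestCoregulatorReduction:
    def test_toy_merges_b_c_after_consistency(self, toy):
        rg = reduce_coregulators(reduce_consistency(toy))
        assert members_of(rg)["B"] == {"B": 1, "C": 1}

    def test_mixed_sign_pair_merges_with_negative_sign(self):
        g = SignedGraph()
        g.add_edge("x", "z", 1)
        g.add_edge("y", "z", -1)
        rg = reduce_coregulators(g)
        assert rg.subcomponents["x"].members == {"x": 1, "y": -1}
        # oracle: in every optimal coloring of the motif x and y are opposite
        for m in enumerate_optimal(g).as_dicts():
            assert m["x"] != m["y"]

    def test_second_successor_blocks_merge(self):
        g = SignedGraph()
        g.add_edge("x", "z", 1)
        g.add_edge("y", "z", 1)
        g.add_edge("y", "w", 1)
        rg = reduce_coregulators(g)
        assert set(members_of(rg)) == {"w", "x", "y", "z"}

    def test_balanced_pair_source_not_treated_as_coregulator(self):
        # a predecessor-free node with +/- edges to the successor is free;
        # merging it with a true co-regulator would drop optimal models
        g = SignedGraph()
        g.add_edge("x", "z", 1)
        g.add_edge("i", "z", 1)
        g.add_edge("i", "z", -1)
        rg = reduce_coregulators(g)
        assert set(members_of(rg)) == {"i", "x", "z"}

    def test_three_coregulators_merge_pairwise(self):
        g = SignedGraph()
        for s, sign in (("x", 1), ("y", -1), ("w", 1)):
            g.add_edge(s, "z", sign)
        rg = reduce_coregulators(g)
        assert rg.subcomponents["w"].members == {"w": 1, "x": 1, "y": -1}


class TestEdgeBalanceReduction:
    def test_toy_isolates_i_and_flags_g(self, toy):
        rg = reduce_all(toy)
        assert set(rg.isolated) == {"I"}
        assert set(rg.connected) == {"A", "B", "D", "G", "H"}
        flag = rg.flags["G"]
        assert flag.always_consistent_imperfect
        assert flag.residual_weight == Fraction(1)

    def test_unequal_pair_leaves_residual_edge_and_flag(self):
        g = SignedGraph()
        g.add_edge("a", "b", 1, 3)
        g.add_edge("a", "b", -1, 1)
        rg = reduce_edge_balance(g)
        assert [(e.sign, e.weight) for e in rg.graph.edges] == [(1, Fraction(2))]
        assert rg.flags["b"].residual_weight == Fraction(1)

    def test_same_sign_weights_already_summed(self):
        g = SignedGraph()
        g.add_edge("a", "b", 1, 1)
        g.add_edge("a", "b", 1, 2)
        rg = reduce_edge_balance(g)
        assert [(e.sign, e.weight) for e in rg.graph.edges] == [(1, Fraction(3))]
        assert rg.flags == {}

    def test_opposite_directions_are_not_a_balanced_pair(self):
        g = SignedGraph()
        g.add_edge("a", "b", 1, 2)
        g.add_edge("b", "a", -1, 2)
        rg = reduce_edge_balance(g)
        assert rg.graph.n_edges() == 2 and rg.flags == {}


class TestReduceAll:
    def test_toy_partition_matches_narrative(self, toy):
        rg = reduce_all(toy)
        assert members_of(rg) == {
            "A": {"A": 1},
            "B": {"B": 1, "C": 1},
            "D": {"D": 1, "E": 1, "F": 1},
            "G": {"G": 1},
            "H": {"H": 1},
            "I": {"I": 1},
        }
        assert set(rg.isolated) == {"I"}

    def test_pattern_free_graph_reduces_to_itself(self):
        g = SignedGraph()
        g.add_edge("a", "c", 1)
        g.add_edge("b", "c", 1)
        g.add_edge("a", "d", 1)   # a has two successors: no co-reg merge
        g.add_edge("b", "d", -1)
        rg = reduce_all(g)
        assert members_of(rg) == {n: {n: 1} for n in "abcd"}
        assert rg.graph == g

    @pytest.mark.parametrize("seed", range(20))
    def test_monotone_shrinkage(self, seed):
        g = random_signed_graph(10, 16, p_inhibition=0.4, weight_range=(1, 3),
                                seed=seed)
        rg = reduce_all(g)
        assert len(rg.subcomponents) <= g.n_nodes()
        assert rg.graph.n_edges() <= g.n_edges()
        assert rg.original_nodes() == g.nodes

    @pytest.mark.parametrize("seed", range(25))
    @pytest.mark.parametrize("rerun", [False, True])
    def test_soundness_on_random_graphs(self, seed, rerun):
        """Expanded reduced-graph optima equal full-graph optima exactly."""
        g = random_signed_graph(6 + seed % 5, 12, p_inhibition=0.5,
                                weight_range=(1, 3), seed=700 + seed)
        full = enumerate_optimal(g)
        rg = reduce_all(g, rerun_after_balance=rerun)
        red = enumerate_optimal(rg.graph, flags=rg.flags)
        exp = expand_model_set(rg, red)
        assert exp.objective == full.objective
        assert exp.colorings == full.colorings


class TestExpandColoring:
    def test_toy_subcomponent_expansion(self, toy):
        rg = reduce_all(toy)
        coloring = {"A": "down", "B": "down", "D": "down", "G": "up",
                    "H": "up", "I": "up"}
        full = expand_coloring(rg, coloring)
        assert full["D"] == full["E"] == full["F"] == "down"
        assert full["B"] == full["C"] == "down"

    def test_negative_relative_sign_flips_member(self):
        g = SignedGraph()
        g.add_edge("a", "b", -1)
        rg = reduce_all(g)
        assert expand_coloring(rg, {"a": "up"}) == {"a": "up", "b": "down"}

    def test_missing_representative_rejected(self, toy):
        rg = reduce_all(toy)
        with pytest.raises(ValueError, match="no color"):
            expand_coloring(rg, {"A": "up"})

    def test_expand_restrict_round_trip(self, toy):
        rg = reduce_all(toy)
        models = enumerate_optimal(rg.graph, flags=rg.flags)
        for m in models.as_dicts():
            full = expand_coloring(rg, m)
            restricted = {rep: full[rep] for rep in rg.subcomponents}
            assert restricted == m
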