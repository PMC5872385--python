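from fractions import Fraction
from itertools import product

import pytest

from perfcolor import (BackendUnavailableError, EnumerationCapError, ModelSet,
                       ObjectiveVector, SignedGraph, TargetFlag,
                       emit_asp_program, enumerate_optimal, evaluate_coloring,
                       explains, flip_coloring, random_signed_graph,
                       target_nodes)
from conftest import TOY_COLORATION_1, single_edge_graph


def oracle_enumerate(graph, fixed=None, flags=None):
    """Independent oracle: score every coloring with evaluate_coloring."""
    nodes = sorted(graph.nodes)
    best = None
    models = []
    for combo in product(("up", "down"), repeat=len(nodes)):
        coloring = dict(zip(nodes, combo))
        if fixed is not None and coloring[fixed[0]] != fixed[1]:
            continue
        obj, _ = evaluate_coloring(graph, coloring, flags)
        key = obj.as_tuple()
        if best is None or key < best:
            best, models = key, [coloring]
        elif key == best:
            models.append(coloring)
    return ModelSet.from_dicts(models, ObjectiveVector(*best), fixed)


class TestExplains:
    @pytest.mark.parametrize("pred,edge,target,expected", [
        ("up", 1, "up", True), ("down", 1, "down", True),
        ("up", 1, "down", False), ("down", 1, "up", False),
        ("up", -1, "down", True), ("down", -1, "up", True),
        ("up", -1, "up", False), ("down", -1, "down", False),
    ])
    def test_truth_table(self, pred, edge, target, expected):
        assert explains(pred, edge, target) is expected


class TestEvaluateColoring:
    def test_toy_coloration_one_objective(self, toy):
        coloring = dict(TOY_COLORATION_1, I="up")
        obj, statuses = evaluate_coloring(toy, coloring)
        assert obj == ObjectiveVector(0, 1, Fraction(1))
        # only G is imperfect, through one of the two opposite I->G edges
        imperfect = {t for t, s in statuses.items() if s.imperfect}
        assert imperfect == {"G"}
        assert statuses["G"].imperfect_regulators == (("I", -1, Fraction(1)),)
        assert all(s.consistent for s in statuses.values())

    def test_single_activation_agreeing(self):
        obj, _ = evaluate_coloring(single_edge_graph(), {"A": "up", "B": "up"})
        assert obj == ObjectiveVector(0, 0, Fraction(0))

    def test_single_activation_conflicting(self):
        obj, statuses = evaluate_coloring(single_edge_graph(),
                                          {"A": "up", "B": "down"})
        assert obj == ObjectiveVector(1, 1, Fraction(1))
        assert not statuses["B"].consistent

    def test_inconsistent_implies_imperfect(self):
        _, statuses = evaluate_coloring(single_edge_graph(),
                                        {"A": "up", "B": "down"})
        for s in statuses.values():
            if not s.consistent:
                assert s.imperfect

    def test_missing_node_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            evaluate_coloring(single_edge_graph(), {"A": "up"})

    def test_flagged_target_always_consistent_imperfect(self):
        g = single_edge_graph()
        flags = {"B": TargetFlag(True, Fraction(2))}
        obj, statuses = evaluate_coloring(g, {"A": "up", "B": "down"}, flags)
        assert statuses["B"].consistent and statuses["B"].imperfect
        # failing edge weight 1 plus stored residual 2
        assert obj == ObjectiveVector(0, 1, Fraction(3))

    def test_flag_on_isolated_node_still_counts(self):
        g = SignedGraph(["X"])
        flags = {"X": TargetFlag(True, Fraction(1))}
        obj, statuses = evaluate_coloring(g, {"X": "up"}, flags)
        assert obj == ObjectiveVector(0, 1, Fraction(1))
        assert statuses["X"].consistent


class TestEnumerateOptimal:
    def test_empty_graph_single_empty_model(self):
        ms = enumerate_optimal(SignedGraph())
        assert len(ms) == 1 and ms.objective == ObjectiveVector(0, 0, Fraction(0))

    def test_cap_refusal_names_the_cap(self):
        g = random_signed_graph(25, 30, seed=0)
        with pytest.raises(EnumerationCapError, match="cap"):
            enumerate_optimal(g, cap=20)

    def test_asp_backend_contract(self, toy):
        # without clingo the backend must fail loudly, never fall back;
        # with clingo it must agree with the brute-force set
        try:
            import clingo  # noqa: F401
        except ImportError:
            with pytest.raises(BackendUnavailableError, match="clingo"):
                enumerate_optimal(toy, backend="asp")
        else:
            ms = enumerate_optimal(toy, backend="asp")
            assert ms.colorings == enumerate_optimal(toy).colorings

    def test_unknown_backend_rejected(self, toy):
        with pytest.raises(ValueError, match="backend"):
            enumerate_optimal(toy, backend="magic")

    def test_fixed_node_filters_models(self):
        g = single_edge_graph()
        ms = enumerate_optimal(g, fixed=("A", "down"))
        assert ms.as_dicts() == [{"A": "down", "B": "down"}]

    def test_fixed_node_must_exist(self):
        with pytest.raises(ValueError, match="fixed"):
            enumerate_optimal(single_edge_graph(), fixed=("Z", "up"))

    @pytest.mark.parametrize("seed", range(15))
    def test_bruteforce_matches_independent_oracle(self, seed):
        g = random_signed_graph(7, 11, p_inhibition=0.5, weight_range=(1, 3),
                                seed=seed)
        got = enumerate_optimal(g)
        want = oracle_enumerate(g)
        assert got.colorings == want.colorings
        assert got.objective == want.objective

    @pytest.mark.parametrize("seed", range(15))
    def test_branchbound_equals_bruteforce(self, seed):
        g = random_signed_graph(8, 13, p_inhibition=0.4, weight_range=(1, 4),
                                seed=100 + seed)
        bf = enumerate_optimal(g, backend="bruteforce")
        bb = enumerate_optimal(g, backend="branchbound")
        assert bf.colorings == bb.colorings
        assert bf.objective == bb.objective

    @pytest.mark.parametrize("seed", range(10))
    def test_unfixed_model_set_is_flip_closed(self, seed):
        g = random_signed_graph(7, 10, p_inhibition=0.5, seed=200 + seed)
        ms = enumerate_optimal(g)
        assert ms.is_flip_closed()

    @pytest.mark.parametrize("seed", range(10))
    def test_flip_preserves_objective(self, seed):
        g = random_signed_graph(6, 9, p_inhibition=0.5, seed=300 + seed)
        ms = enumerate_optimal(g)
        for m in ms.as_dicts():
            obj, _ = evaluate_coloring(g, flip_coloring(m))
            assert obj == ms.objective

    @pytest.mark.parametrize("seed", range(10))
    def test_returned_models_reproduce_stored_objective(self, seed):
        g = random_signed_graph(7, 12, p_inhibition=0.3, weight_range=(1, 5),
                                seed=400 + seed)
        ms = enumerate_optimal(g)
        for m in ms.as_dicts():
            obj, _ = evaluate_coloring(g, m)
            assert obj == ms.objective

    def test_zero_inconsistency_reached_when_explainable(self):
        # a DAG always admits a fully consistent coloring
        for seed in range(8):
            g = random_signed_graph(8, 10, p_inhibition=0.5, seed=500 + seed)
            ms = enumerate_optimal(g)
            has_cycle = False
            import networkx as nx
            has_cycle = not nx.is_directed_acyclic_graph(
                nx.DiGraph((e.source, e.target) for e in g.edges))
            if not has_cycle:
                assert ms.objective.n_inconsistent == 0


class TestEmitAspProgram:
    def test_program_structure(self, toy):
        text = emit_asp_program(toy)
        assert 'edge("B","D",1,1).' in text
        assert "1 { color(X,S) : sign(S) } 1 :- node(X)." in text
        assert "#minimize { 1@3,T : inconsistent(T) }." in text
        assert "#minimize { 1@2,T : imperfect(T) }." in text
        assert "#minimize { W@1,S,T : imperfect_reg(S,T,W) }." in text

    def test_empty_graph_program_has_no_edge_facts(self):
        text = emit_asp_program(SignedGraph())
        assert not any(line.startswith("edge(") for line in text.splitlines())
        assert "1 { color(X,S) : sign(S) } 1 :- node(X)." in text

    def test_fixing_fact_emitted(self, toy):
        text = emit_asp_program(toy, fixed=("A", "down"))
        assert 'color("A",down).' in text

    def test_flags_and_scaled_weights(self):
        g = SignedGraph()
        g.add_edge("A", "B", 1, Fraction(1, 2))
        text = emit_asp_program(g, flags={"B": TargetFlag(True, Fraction(3, 2))})
        assert "% weight scale: 2" in text
        assert 'edge("A","B",1,1).' in text
        assert 'flagged("B").' in text
        assert 'residual("B",3).' in text
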