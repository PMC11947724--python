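"""Topological planning, the three matchers, verification and MeanVal."""

import numpy as np
import pytest

import kgmatch as km
from kgmatch.errors import KGMatchError, NotADAGError

from conftest import make_random_graph

VACUOUS = km.MCConfig(n_draws=200, top_n=10**6, seed=0)


def path_set(sub):
    return {(pe, q.node_sequence) for pe, qs in sub.edge_paths.items() for q in qs}


def identity_set(result):
    return {sub.identity() for sub in result.subgraphs}


def weakly_contained(sub, candidates):
    """sub's assignments and paths all appear within some candidate subgraph."""
    return any(
        all(sub.assignment[u] <= b.assignment.get(u, frozenset()) for u in sub.assignment)
        and path_set(sub) <= path_set(b)
        for b in candidates
    )


def planted_five_node_graph():
    """Exactly one embedding of the consultation pattern, plus role decoys."""
    g = km.DataGraph()
    for role in ("AP", "TI", "TC", "PM", "TM"):
        g.add_node(km.DataNode(id=role.lower(), role=role, dt=0.5))
    for i in range(3):
        g.add_node(km.DataNode(id=f"decoy{i}", role="XX", dt=0.9))
    for src, tgt in (("ap", "ti"), ("ap", "tc"), ("ti", "tc"), ("pm", "tc"), ("tc", "tm")):
        g.add_edge(km.DataEdge(source=src, target=tgt, dt_trust=0.5, dc=0.5, cv=0.5))
    return g


class TestTopologicalPlan:
    def test_consultation_pattern_sources(self, pattern):
        plan = km.topological_plan(pattern)
        assert set(plan.sources) == {"AP", "PM"}
        assert plan.start_node == "AP"

    def test_order_respects_instrument_confirms_tumor_edge(self, pattern):
        plan = km.topological_plan(pattern)
        assert plan.order.index("TI") < plan.order.index("TC")

    def test_single_node_pattern(self):
        p = km.PatternGraph()
        p.add_node(km.PatternNode(id="only", role="AP"))
        plan = km.topological_plan(p)
        assert plan.order == ("only",) and plan.sources == ("only",)

    def test_cycle_raises(self):
        p = km.PatternGraph()
        p.add_node(km.PatternNode(id="u", role="AP"))
        p.add_node(km.PatternNode(id="w", role="TC"))
        p.add_edge(km.PatternEdge(source="u", target="w"))
        p.add_edge(km.PatternEdge(source="w", target="u"))
        with pytest.raises(NotADAGError):
            km.topological_plan(p)


class TestMatchers:
    def test_unique_planted_embedding_is_recovered_exactly(self):
        g = planted_five_node_graph()
        p = km.reference_pattern(node_threshold=0.0, edge_threshold=0.0)
        result = km.tem_match(g, p, VACUOUS)
        assert len(result) == 1
        (sub,) = result.subgraphs
        assert sub.assignment == {
            "AP": frozenset({"ap"}),
            "TI": frozenset({"ti"}),
            "TC": frozenset({"tc"}),
            "PM": frozenset({"pm"}),
            "TM": frozenset({"tm"}),
        }
        assert identity_set(km.baseline_match(g, p)) == identity_set(result)

    def test_absent_pattern_role_yields_empty_result(self, toy_graph):
        p = km.PatternGraph()
        p.add_node(km.PatternNode(id="u", role="ZZ"))
        assert len(km.tem_match(toy_graph, p)) == 0

    def test_matchers_are_deterministic_under_seed(self, toy_graph, pattern):
        for fn in (km.tem_match, km.thm_match):
            cfg = km.MCConfig(n_draws=300, top_n=1, seed=17)
            a, b = fn(toy_graph, pattern, cfg), fn(toy_graph, pattern, cfg)
            assert identity_set(a) == identity_set(b)
            assert a.draws_consumed == b.draws_consumed

    def test_degenerate_mc_collapses_to_baseline(self):
        p = km.reference_pattern(node_threshold=0.0, edge_threshold=0.0)
        for seed in range(10):
            g = make_random_graph(seed, p=0.4)
            base = identity_set(km.baseline_match(g, p))
            assert identity_set(km.tem_match(g, p, VACUOUS)) == base
            assert identity_set(km.thm_match(g, p, VACUOUS)) == base

    def test_stochastic_results_weakly_contained_in_baseline(self, pattern):
        for seed in range(10):
            g = make_random_graph(seed, p=0.45, planted=1)
            base = km.baseline_match(g, pattern).subgraphs
            cfg = km.MCConfig(n_draws=200, top_n=1, seed=seed)
            for fn in (km.tem_match, km.thm_match):
                for sub in fn(g, pattern, cfg).subgraphs:
                    assert weakly_contained(sub, base)

    def test_limit_is_a_prefix_of_the_full_run(self, pattern):
        g = make_random_graph(2, sizes={"AP": 4, "TI": 3, "TC": 3, "PM": 3, "TM": 3}, p=0.5, planted=2)
        full = km.baseline_match(g, pattern)
        assert len(full) >= 2
        limited = km.baseline_match(g, pattern, limit=2)
        assert [s.identity() for s in limited.subgraphs] == [
            s.identity() for s in full.subgraphs[:2]
        ]

    def test_single_candidate_everywhere_makes_thm_equal_tem(self, toy_graph, pattern):
        cfg = km.MCConfig(n_draws=100, top_n=1, seed=5)
        assert identity_set(km.thm_match(toy_graph, pattern, cfg)) == identity_set(
            km.tem_match(toy_graph, pattern, cfg)
        )


class TestVerification:
    def test_matcher_output_verifies(self, toy_graph, pattern):
        result = km.tem_match(toy_graph, pattern)
        assert result.subgraphs
        for sub in result.subgraphs:
            assert km.verify_match(sub, toy_graph, pattern)

    def test_overlong_path_is_reported(self, toy_graph, pattern):
        (sub,) = km.tem_match(toy_graph, pattern, VACUOUS).subgraphs
        bad = km.MatchSubgraph(dict(sub.assignment), dict(sub.edge_paths))
        three_hop = km.PathMatch(("AP", "TC"), ("Helen", "RATS", "SLCLIA", "Drug"), 0.5, 0.5, 0.5)
        bad.edge_paths[("AP", "TC")] = (three_hop,)
        report = km.verify_match(bad, toy_graph, pattern)
        assert not report.ok
        assert any("hops" in v for v in report.violations)

    def test_missing_assignment_is_reported(self, toy_graph, pattern):
        (sub,) = km.tem_match(toy_graph, pattern, VACUOUS).subgraphs
        assignment = dict(sub.assignment)
        del assignment["PM"]
        report = km.verify_match(km.MatchSubgraph(assignment, dict(sub.edge_paths)), toy_graph, pattern)
        assert not report.ok
        assert any("PM" in v and "no assigned" in v for v in report.violations)

    def test_tampered_aggregates_are_reported(self, toy_graph, pattern):
        (sub,) = km.tem_match(toy_graph, pattern, VACUOUS).subgraphs
        edge_paths = dict(sub.edge_paths)
        q = edge_paths[("TC", "TM")][0]
        edge_paths[("TC", "TM")] = (
            km.PathMatch(q.pattern_edge, q.node_sequence, q.a_dt, 0.99, q.a_cv),
        ) + edge_paths[("TC", "TM")][1:]
        report = km.verify_match(km.MatchSubgraph(dict(sub.assignment), edge_paths), toy_graph, pattern)
        assert not report.ok
        assert any("disagree" in v for v in report.violations)


class TestMeanVal:
    def test_constant_attribute_field_gives_that_constant(self):
        # hop bound 1 so every matched path is a single edge: products of a
        # constant field stay constant only without multi-hop aggregation
        g = planted_five_node_graph()
        p = km.reference_pattern(node_threshold=0.0, edge_threshold=0.0, length_bound=1)
        result = km.tem_match(g, p, VACUOUS)
        summary = km.meanval_statistic(result, sample_edges=1000)
        assert summary.meanval == pytest.approx(0.5)

    def test_full_sample_is_exact_mean(self):
        pe = ("TC", "TM")
        paths = (
            km.PathMatch(pe, ("s", "a"), 0.5, 0.8, 0.6),
            km.PathMatch(pe, ("s", "b"), 0.5, 0.4, 0.2),
        )
        sub = km.MatchSubgraph({"TC": frozenset({"s"}), "TM": frozenset({"a", "b"})}, {pe: paths})
        result = km.MatchResult([sub], "tem", km.MCConfig(), 0)
        summary = km.meanval_statistic(result, sample_edges=2)
        assert summary.meanval == pytest.approx(0.5)
        assert summary.n_paths == 2

    def test_subsampling_is_seeded_and_bounded(self, toy_graph, pattern):
        result = km.tem_match(toy_graph, pattern, VACUOUS)
        one = km.meanval_statistic(result, 3, np.random.default_rng(1))
        two = km.meanval_statistic(result, 3, np.random.default_rng(1))
        assert one == two and one.n_paths == 3

    def test_empty_result_raises(self):
        empty = km.MatchResult([], "tem", km.MCConfig(), 0)
        with pytest.raises(KGMatchError):
            km.meanval_statistic(empty, 10)


class TestSerialization:
    def test_result_round_trips_through_dict(self, toy_graph, pattern):
        result = km.tem_match(toy_graph, pattern, km.MCConfig(seed=3))
        back = km.result_from_dict(km.result_to_dict(result))
        assert identity_set(back) == identity_set(result)
        assert back.algorithm == result.algorithm
        assert back.config == result.config
        assert back.draws_consumed == result.draws_consumed
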