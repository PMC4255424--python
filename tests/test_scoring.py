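import math
from fractions import Fraction

import numpy as np
import pytest

from prstool.fixtures import duplicate_gene_definition, signalling_definition
from prstool.graph_build import build_signalling_graph
from prstool.expression import Universe
from prstool.scoring import (
    assess_nodes,
    compute_prs,
    compute_zscore,
    rank_by_prs,
    rank_by_zscore,
    score_all,
    score_pathway,
)

from conftest import brute_force_downstream, make_graph, random_digraph, stats_for


def reference_zscore(n, f, T, F):
    """Independent closed-form evaluation using exact rational arithmetic."""
    rate = Fraction(F, T)
    mean = n * rate
    var = n * rate * (1 - rate) * (1 - Fraction(n - 1, T - 1))
    if var == 0:
        return math.nan
    return float((Fraction(f) - mean) / Fraction(math.sqrt(var)))


class TestAssessNodes:
    def test_terminal_significant_node_weight_one(self):
        g = make_graph([("a", "b")])
        out = {a.node_id: a for a in assess_nodes(g, stats_for({"b": 2.0}))}
        assert out["b"].weight == 1
        assert out["a"].weight == 0

    def test_chain_weights(self):
        g = make_graph([("a", "b"), ("b", "c")])
        stats = stats_for({"a": 2.0, "b": 3.0, "c": 1.5})
        weights = [x.weight for x in assess_nodes(g, stats)]
        assert weights == [3, 2, 1]

    def test_non_significant_node_defaults(self):
        g = make_graph([("a", "b")])
        out = {x.node_id: x for x in assess_nodes(g, stats_for({}, nonsig=["a", "b"]))}
        assert out["a"].weight == 0
        assert out["a"].fc_magnitude == 1.0
        assert not out["a"].significant

    def test_multigene_node_any_significant_max_magnitude(self):
        from prstool.graph_build import GeneNode, PathwayGraph

        g = PathwayGraph(
            "p", "p", "signalling",
            nodes={"m": GeneNode("m", frozenset({"g1", "g2", "g3"}), frozenset())},
            edges=set(),
        )
        stats = stats_for({"g1": 1.5, "g2": 4.0}, nonsig=["g3"])
        (a,) = assess_nodes(g, stats)
        assert a.significant
        assert a.fc_magnitude == 4.0


class TestComputePrs:
    def test_chain_worked_example(self):
        g = make_graph([("a", "b"), ("b", "c")])
        stats = stats_for({"a": 2.0, "b": 3.0, "c": 1.5})
        prs_raw, prs = compute_prs(assess_nodes(g, stats), g.node_count)
        assert prs_raw == pytest.approx(13.5)
        assert prs == pytest.approx(4.5)

    def test_cycle_worked_example(self):
        g = make_graph([("a", "b"), ("b", "c"), ("c", "a")])
        stats = stats_for({"a": 2.0, "b": 2.0, "c": 2.0})
        prs_raw, prs = compute_prs(assess_nodes(g, stats), g.node_count)
        assert prs_raw == pytest.approx(18.0)
        assert prs == pytest.approx(6.0)

    def test_no_significant_nodes_zero(self):
        g = make_graph([("a", "b")])
        assert compute_prs(assess_nodes(g, stats_for({}, ["a", "b"])), 2) == (0, 0)

    def test_zero_node_count_rejected(self):
        with pytest.raises(ValueError):
            compute_prs([], 0)


class TestZScore:
    def test_expectation_gives_zero(self):
        assert compute_zscore(10, 1, 1000, 100) == 0.0

    def test_enrichment_worked_example(self):
        assert compute_zscore(10, 5, 1000, 100) == pytest.approx(4.235, abs=1e-3)

    def test_depletion_negative(self):
        assert compute_zscore(10, 0, 1000, 100) < 0

    def test_variance_zero_returns_nan(self):
        assert math.isnan(compute_zscore(10, 0, 1000, 0))
        assert math.isnan(compute_zscore(10, 10, 1000, 1000))

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_zscore(0, 0, 1000, 100)
        with pytest.raises(ValueError):
            compute_zscore(1000, 5, 1000, 100)

    def test_matches_independent_formula_on_random_tuples(self):
        rng = np.random.default_rng(99)
        for _ in range(1000):
            T = int(rng.integers(10, 5000))
            n = int(rng.integers(1, T))
            F = int(rng.integers(0, T + 1))
            f = int(rng.integers(0, n + 1))
            got = compute_zscore(n, f, T, F)
            want = reference_zscore(n, f, T, F)
            if math.isnan(want):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-12, rel=1e-12)


class TestScoreAll:
    def test_weight_vector_matches_oracle_on_random_graphs(self):
        rng = np.random.default_rng(555)
        for _ in range(50):
            graph, significant = random_digraph(rng)
            stats = stats_for(
                {g: 2.0 for g in significant},
                nonsig=[n for n in graph.nodes if n not in significant],
            )
            for a in assess_nodes(graph, stats):
                if a.significant:
                    want = 1 + brute_force_downstream(graph, a.node_id, significant)
                    assert a.weight == want
                else:
                    assert a.weight == 0

    def test_rankings_and_na_policy(self):
        g1 = make_graph([("a", "b"), ("b", "c")], pathway_id="p1")
        g2 = make_graph([("d", "e")], pathway_id="p2")
        g3 = make_graph([("f", "h")], pathway_id="p3")
        stats = stats_for({"a": 2.0, "b": 3.0, "c": 1.5, "d": 2.0},
                          nonsig=["e", "f", "h"])
        universe = Universe(T=200, F=4)
        scores = score_all([g1, g2, g3], stats, universe)
        prs_order = [s.pathway_id for s in rank_by_prs(scores)]
        assert prs_order == ["p1", "p2", "p3"]
        # p3 has f=0 but defined z (negative); ordering is by z desc
        z_order = [s.pathway_id for s in rank_by_zscore(scores)]
        assert z_order[0] in {"p1", "p2"}

    def test_undefined_z_placed_last(self):
        g1 = make_graph([("a", "b")], pathway_id="p1")
        g2 = make_graph([("c", "d")], pathway_id="p2")
        stats = stats_for({}, nonsig=["a", "b", "c", "d"])
        universe = Universe(T=100, F=0)  # variance vanishes: z undefined
        scores = score_all([g1, g2], stats, universe)
        assert all(not s.z_defined for s in scores)
        assert [s.pathway_id for s in rank_by_zscore(scores)] == ["p1", "p2"]

    def test_score_ties_broken_by_pathway_id(self):
        g1 = make_graph([("a", "b")], pathway_id="pB")
        g2 = make_graph([("c", "d")], pathway_id="pA")
        stats = stats_for({}, nonsig=["a", "b", "c", "d"])
        scores = score_all([g1, g2], stats, Universe(T=100, F=1))
        assert [s.pathway_id for s in rank_by_prs(scores)] == ["pA", "pB"]

    def test_prs_invariant_to_duplicated_kgml_entry(self):
        base = signalling_definition(
            "hsa90900", ["9101", "9102", "9103"], [(0, 1), (1, 2)]
        )
        dup = duplicate_gene_definition("hsa90900")
        stats = stats_for({"9101": 2.0, "9102": 3.0, "9103": 1.5})
        universe = Universe(T=100, F=3)
        s_base = score_pathway(build_signalling_graph(base), stats, universe)
        s_dup = score_pathway(build_signalling_graph(dup), stats, universe)
        assert s_base.node_count == s_dup.node_count
        assert s_base.prs == s_dup.prs
        assert s_base.z_score == s_dup.z_score

    def test_prs_monotone_in_magnitude_and_edges(self):
        stats_lo = stats_for({"a": 2.0, "b": 1.5}, nonsig=["c"])
        stats_hi = stats_for({"a": 3.0, "b": 1.5}, nonsig=["c"])
        universe = Universe(T=50, F=2)
        g = make_graph([("a", "b")], nodes=["a", "b", "c"])
        lo = score_pathway(g, stats_lo, universe).prs
        hi = score_pathway(g, stats_hi, universe).prs
        assert hi >= lo
        g_more = make_graph([("a", "b"), ("b", "a")], nodes=["a", "b", "c"])
        more = score_pathway(g_more, stats_lo, universe).prs
        assert more >= lo
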