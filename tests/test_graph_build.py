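import numpy as np
import pytest

from prstool.fixtures import duplicate_gene_definition, group_entry_definition
from prstool.graph_build import (
    EmptyPathwayError,
    deduplicate_nodes,
    downstream_significant_count,
    build_metabolic_graph,
    build_signalling_graph,
)
from prstool.kgml_io import (
    KgmlEntry,
    KgmlReaction,
    KgmlRelation,
    PathwayDefinition,
    parse_kgml,
)

from conftest import brute_force_downstream, make_graph


def signalling_defn(genes_by_entry, relations, extra_entries=()):
    entries = [
        KgmlEntry(eid, "gene", tuple(genes), raw_names=tuple(f"hsa:{g}" for g in genes))
        for eid, genes in genes_by_entry.items()
    ]
    entries.extend(extra_entries)
    return PathwayDefinition(
        kegg_id="hsa00099",
        title="t",
        organism_code="hsa",
        entries=entries,
        relations=[KgmlRelation(a, b, "PPrel") for a, b in relations],
    )


class TestSignallingGraph:
    def test_chain(self):
        defn = signalling_defn(
            {"1": ["a"], "2": ["b"], "3": ["c"]}, [("1", "2"), ("2", "3")]
        )
        g = build_signalling_graph(defn)
        assert g.node_count == 3
        assert g.edges == {("a", "b"), ("b", "c")}

    def test_cycle_preserved(self):
        defn = signalling_defn({"1": ["a"], "2": ["b"]}, [("1", "2"), ("2", "1")])
        g = build_signalling_graph(defn)
        assert g.node_count == 2
        assert g.edges == {("a", "b"), ("b", "a")}

    def test_group_expansion_fans_out(self):
        g = build_signalling_graph(group_entry_definition())
        # relation e1 -> group{e2,e3} becomes edges to both components
        assert g.edges == {("9301", "9302"), ("9301", "9303")}

    def test_relations_to_compound_and_map_dropped(self):
        extra = (
            KgmlEntry("c1", "compound", raw_names=("cpd:C00001",)),
            KgmlEntry("m1", "map", raw_names=("path:hsa00010",)),
        )
        defn = signalling_defn(
            {"1": ["a"], "2": ["b"]},
            [("1", "c1"), ("c1", "2"), ("1", "m1"), ("1", "2")],
            extra_entries=extra,
        )
        g = build_signalling_graph(defn)
        assert g.edges == {("a", "b")}

    def test_zero_gene_entries_raises_empty_signal(self):
        defn = PathwayDefinition(
            "hsa00098", "t", "hsa",
            entries=[KgmlEntry("c1", "compound")],
        )
        with pytest.raises(EmptyPathwayError):
            build_signalling_graph(defn)


def metabolic_defn(reactions, entries):
    return PathwayDefinition(
        kegg_id="hsa00097", title="m", organism_code="hsa",
        entries=entries, reactions=reactions,
    )


def enzyme(eid, gene, *rxns):
    return KgmlEntry(eid, "gene", (gene,), raw_names=(f"hsa:{gene}",),
                     reaction_names=tuple(rxns))


class TestMetabolicGraph:
    def test_product_substrate_chaining(self):
        defn = metabolic_defn(
            [
                KgmlReaction("R1", ("1",), ("C1",), ("C2",)),
                KgmlReaction("R2", ("2",), ("C2",), ("C3",)),
            ],
            [enzyme("1", "a", "R1"), enzyme("2", "b", "R2")],
        )
        g = build_metabolic_graph(defn)
        assert set(g.nodes) == {"a", "b"}
        assert g.edges == {("a", "b")}

    def test_reversible_reaction_symmetric_compounds(self):
        # R1 reversible C1<->C2 by E1; R2: C2->C3 by E2; C3 does not feed back
        defn = metabolic_defn(
            [
                KgmlReaction("R1", ("1",), ("C1",), ("C2",), reversible=True),
                KgmlReaction("R2", ("2",), ("C2",), ("C3",)),
            ],
            [enzyme("1", "a", "R1"), enzyme("2", "b", "R2")],
        )
        g = build_metabolic_graph(defn)
        assert g.edges == {("a", "b")}

    def test_single_reaction_single_enzyme_no_edges(self):
        defn = metabolic_defn(
            [KgmlReaction("R1", ("1",), ("C1",), ("C2",))],
            [enzyme("1", "a", "R1")],
        )
        g = build_metabolic_graph(defn)
        assert g.node_count == 1
        assert g.edges == set()

    def test_ecrel_relation_contributes_edges(self):
        defn = metabolic_defn(
            [KgmlReaction("R1", ("1",), ("C1",), ("C2",))],
            [enzyme("1", "a", "R1"), enzyme("2", "b")],
        )
        defn.relations = [KgmlRelation("1", "2", "ECrel")]
        g = build_metabolic_graph(defn)
        assert g.edges == {("a", "b")}


class TestDeduplication:
    def test_shared_gene_merges_with_edge_union(self):
        defn = signalling_defn(
            {"e1": ["g"], "e2": ["g"], "x": ["x"], "y": ["y"]},
            [("e1", "x"), ("y", "e2")],
        )
        g = build_signalling_graph(defn)
        assert set(g.nodes) == {"g", "x", "y"}
        assert g.edges == {("g", "x"), ("y", "g")}
        assert g.nodes["g"].source_entry_ids == frozenset({"e1", "e2"})

    def test_no_duplicates_identity(self):
        g = make_graph([("a", "b"), ("b", "c")])
        d = deduplicate_nodes(g)
        assert set(d.nodes) == set(g.nodes)
        assert d.edges == g.edges

    def test_merge_removes_resulting_self_edge(self):
        defn = signalling_defn({"e1": ["g"], "e2": ["g"]}, [("e1", "e2")])
        g = build_signalling_graph(defn)
        assert set(g.nodes) == {"g"}
        assert g.edges == set()

    def test_idempotent(self):
        defn = signalling_defn(
            {"e1": ["g", "h"], "e2": ["h", "k"], "e3": ["m"]},
            [("e1", "e3"), ("e3", "e2")],
        )
        g = build_signalling_graph(defn)
        again = deduplicate_nodes(g)
        assert set(again.nodes) == set(g.nodes)
        assert again.edges == g.edges

    def test_duplicate_gene_fixture_post_dedup_node_count(self):
        defn = duplicate_gene_definition()
        g = build_signalling_graph(defn)
        distinct_genes = {gg for e in defn.entries for gg in e.gene_ids}
        assert g.node_count == len(distinct_genes)
        # merged node keeps both the in-edge and the out-edge
        assert g.edges == {("9101", "9102"), ("9102", "9103")}

    def test_conservation_on_random_provisional_graphs(self):
        """Gene sets survive as a set; every cross-node edge survives the merge."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            n_entries = int(rng.integers(2, 10))
            n_genes = int(rng.integers(1, 6))
            genes_by_entry = {
                f"e{i}": [str(rng.integers(0, n_genes))] for i in range(n_entries)
            }
            relations = [
                (f"e{int(rng.integers(n_entries))}", f"e{int(rng.integers(n_entries))}")
                for _ in range(int(rng.integers(0, 12)))
            ]
            defn = signalling_defn(genes_by_entry, relations)
            g = build_signalling_graph(defn)
            all_genes = {gg for gs in genes_by_entry.values() for gg in gs}
            assert g.gene_ids() == all_genes
            # every gene in exactly one node
            seen = [gg for nid in g.nodes for gg in g.nodes[nid].gene_ids]
            assert len(seen) == len(set(seen))
            gene_to_node = {gg: nid for nid in g.nodes for gg in g.nodes[nid].gene_ids}
            for a, b in relations:
                na = gene_to_node[genes_by_entry[a][0]]
                nb = gene_to_node[genes_by_entry[b][0]]
                if na != nb:
                    assert (na, nb) in g.edges


class TestDownstreamSignificantCount:
    def test_chain_all_significant(self):
        g = make_graph([("a", "b"), ("b", "c")])
        assert downstream_significant_count(g, "a", {"a", "b", "c"}) == 2

    def test_cycle_counted_once(self):
        g = make_graph([("a", "b"), ("b", "c"), ("c", "a")])
        for node in "abc":
            assert downstream_significant_count(g, node, {"a", "b", "c"}) == 2

    def test_nonsignificant_intermediate_blocks(self):
        g = make_graph([("a", "x"), ("x", "b")])
        assert downstream_significant_count(g, "a", {"a", "b"}) == 0

    def test_nonsignificant_intermediate_allowed_with_switch(self):
        g = make_graph([("a", "x"), ("x", "b")])
        assert downstream_significant_count(
            g, "a", {"a", "b"}, through_significant_only=False
        ) == 1

    def test_missing_node_raises(self):
        g = make_graph([("a", "b")])
        with pytest.raises(KeyError):
            downstream_significant_count(g, "zz", {"a"})

    @pytest.mark.parametrize("through_sig", [True, False])
    def test_oracle_equivalence_random_digraphs(self, through_sig):
        """DFS count equals brute-force transitive closure on 200 random digraphs."""
        from conftest import random_digraph

        rng = np.random.default_rng(1234 + int(through_sig))
        for _ in range(200):
            graph, significant = random_digraph(rng)
            for node in significant:
                got = downstream_significant_count(
                    graph, node, significant, through_significant_only=through_sig
                )
                want = brute_force_downstream(
                    graph, node, significant, through_significant_only=through_sig
                )
                assert got == want

    def test_termination_on_complete_cyclic_graph(self):
        nodes = [f"n{i}" for i in range(100)]
        edges = [(a, b) for a in nodes for b in nodes if a != b]
        g = make_graph(edges)
        assert downstream_significant_count(g, "n0", set(nodes)) == 99
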