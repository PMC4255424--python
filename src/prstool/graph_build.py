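"""Conversion of parsed pathways into deduplicated directed gene graphs.

Signalling pathways: gene entries become nodes and relations become directed
edges.  Metabolic pathways: enzymes become nodes and an edge E1 -> E2 is drawn
whenever a product compound of a reaction catalysed by E1 is a substrate of a
reaction catalysed by E2 (substrate/product chaining); enzyme-enzyme (ECrel)
relations contribute edges too.

After edge creation every graph is deduplicated so that each gene appears in
exactly one node: all nodes sharing a gene are merged transitively, edges are
unioned, and self-edges introduced by the merge are removed.  Deduplication is
what keeps highly redundant KEGG descriptions (the same gene drawn in several
boxes) from inflating pathway scores.

The topological weight of a differentially-expressed node is based on
:func:`downstream_significant_count` -- a depth-first search that counts the
distinct significant nodes reachable from it; a visited set guarantees loops
are counted once and the walk terminates on cyclic graphs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

from .kgml_io import (
    METABOLIC,
    SIGNALLING,
    GENE_LIKE_TYPES,
    KgmlEntry,
    PathwayDefinition,
)

logger = logging.getLogger(__name__)


class EmptyPathwayError(Exception):
    """Raised when a pathway yields no gene nodes and cannot be scored."""


@dataclass(frozen=True)
class GeneNode:
    """A graph node covering one or more genes merged from pathway entries."""

    node_id: str
    gene_ids: frozenset[str]
    source_entry_ids: frozenset[str]


@dataclass
class PathwayGraph:
    """Directed gene graph for one pathway."""

    pathway_id: str
    title: str
    category: str
    nodes: dict[str, GeneNode]
    edges: set[tuple[str, str]]
    _adjacency: dict[str, tuple[str, ...]] | None = field(
        default=None, repr=False, compare=False
    )

    @property
    def node_count(self) -> int:
        return len(self.nodes)

    def gene_ids(self) -> set[str]:
        out: set[str] = set()
        for node in self.nodes.values():
            out |= node.gene_ids
        return out

    def adjacency(self) -> dict[str, tuple[str, ...]]:
        """Children of every node, sorted for deterministic traversal."""
        if self._adjacency is None:
            adj: dict[str, list[str]] = {nid: [] for nid in self.nodes}
            for src, dst in sorted(self.edges):
                adj[src].append(dst)
            self._adjacency = {nid: tuple(children) for nid, children in adj.items()}
        return self._adjacency

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(sorted(self.nodes))
        g.add_edges_from(sorted(self.edges))
        return g

    def write_edge_list_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for src, dst in sorted(self.edges):
                fh.write(f"{src}\t{dst}\n")

    def write_node_table_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for nid in sorted(self.nodes):
                fh.write(f"{nid}\t{','.join(sorted(self.nodes[nid].gene_ids))}\n")


def _expand_to_gene_entries(
    entry_id: str, entry_map: dict[str, KgmlEntry], _seen: frozenset[str] = frozenset()
) -> list[str]:
    """Resolve an entry id to gene-entry ids, fanning groups out recursively.

    Map and compound entries resolve to nothing; relations touching them are
    thereby dropped.
    """
    entry = entry_map.get(entry_id)
    if entry is None or entry_id in _seen:
        return []
    if entry.is_gene_like:
        return [entry_id]
    if entry.entry_type == "group":
        out: list[str] = []
        for comp in entry.component_ids:
            out.extend(_expand_to_gene_entries(comp, entry_map, _seen | {entry_id}))
        return out
    return []


def _provisional_graph(
    defn: PathwayDefinition, entry_edges: set[tuple[str, str]]
) -> PathwayGraph:
    nodes = {
        e.entry_id: GeneNode(
            node_id=e.entry_id,
            gene_ids=frozenset(e.gene_ids),
            source_entry_ids=frozenset({e.entry_id}),
        )
        for e in defn.entries
        if e.is_gene_like
    }
    edges = {
        (src, dst)
        for src, dst in entry_edges
        if src != dst and src in nodes and dst in nodes
    }
    return PathwayGraph(
        pathway_id=defn.kegg_id,
        title=defn.title,
        category=defn.category,
        nodes=nodes,
        edges=edges,
    )


def build_signalling_graph(defn: PathwayDefinition) -> PathwayGraph:
    """Build the deduplicated gene graph of a signalling pathway.

    Each relation entry1 -> entry2 becomes one edge per resolved gene-entry
    pair; groups fan out to all their gene components; relations touching map
    or compound entries are dropped.
    """
    entry_map = defn.entry_map()
    edges: set[tuple[str, str]] = set()
    for rel in defn.relations:
        sources = _expand_to_gene_entries(rel.entry1_id, entry_map)
        targets = _expand_to_gene_entries(rel.entry2_id, entry_map)
        for s in sources:
            for t in targets:
                edges.add((s, t))
    graph = _provisional_graph(defn, edges)
    if not graph.nodes:
        raise EmptyPathwayError(f"{defn.kegg_id}: no gene entries")
    return deduplicate_nodes(graph)


def build_metabolic_graph(defn: PathwayDefinition) -> PathwayGraph:
    """Build the deduplicated enzyme graph of a metabolic pathway.

    An edge E1 -> E2 is drawn whenever some product of a reaction catalysed by
    E1 is a substrate of a reaction catalysed by E2.  Compounds on both sides
    of a reversible reaction act as both substrates and products (direction is
    undefined for reversible steps).  ECrel relations between enzyme entries
    add edges the same way signalling relations do; self-edges are discarded.
    """
    entry_map = defn.entry_map()
    edges: set[tuple[str, str]] = set()

    effective: list[tuple[tuple[str, ...], frozenset[str], frozenset[str]]] = []
    for rx in defn.reactions:
        subs = frozenset(rx.substrate_ids)
        prods = frozenset(rx.product_ids)
        if rx.reversible:
            subs = prods = subs | prods
        effective.append((rx.enzyme_entry_ids, subs, prods))

    for enz1, _, prods1 in effective:
        for enz2, subs2, _ in effective:
            if not prods1 & subs2:
                continue
            for e1 in enz1:
                for e2 in enz2:
                    if e1 != e2:
                        edges.add((e1, e2))

    for rel in defn.relations:
        sources = _expand_to_gene_entries(rel.entry1_id, entry_map)
        targets = _expand_to_gene_entries(rel.entry2_id, entry_map)
        for s in sources:
            for t in targets:
                edges.add((s, t))

    graph = _provisional_graph(defn, edges)
    if not graph.nodes:
        raise EmptyPathwayError(f"{defn.kegg_id}: no enzyme entries")
    return deduplicate_nodes(graph)


def build_graph(defn: PathwayDefinition) -> PathwayGraph:
    """Dispatch on pathway category."""
    if defn.category == METABOLIC:
        return build_metabolic_graph(defn)
    return build_signalling_graph(defn)


def deduplicate_nodes(graph: PathwayGraph) -> PathwayGraph:
    """Merge all nodes sharing any gene ID so each gene appears exactly once.

    Merging is transitive (union-find over shared genes); the merged node's
    edge set is the union of its members' in- and out-edges, duplicate edges
    collapse, and self-edges created by the merge are removed.  The merged
    node takes the lexicographically smallest member gene ID as its id, which
    makes output ordering deterministic.  Idempotent.
    """
    parent: dict[str, str] = {nid: nid for nid in graph.nodes}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    owner: dict[str, str] = {}  # gene -> representative node
    for nid in sorted(graph.nodes):
        for gene in graph.nodes[nid].gene_ids:
            if gene in owner:
                union(owner[gene], nid)
            else:
                owner[gene] = nid

    groups: dict[str, list[str]] = {}
    for nid in graph.nodes:
        groups.setdefault(find(nid), []).append(nid)

    new_id: dict[str, str] = {}  # old node id -> merged node id
    merged: dict[str, GeneNode] = {}
    for members in groups.values():
        genes: set[str] = set()
        sources: set[str] = set()
        for nid in members:
            genes |= graph.nodes[nid].gene_ids
            sources |= graph.nodes[nid].source_entry_ids
        node_id = min(genes)
        merged[node_id] = GeneNode(
            node_id=node_id,
            gene_ids=frozenset(genes),
            source_entry_ids=frozenset(sources),
        )
        for nid in members:
            new_id[nid] = node_id

    edges = {
        (new_id[s], new_id[t])
        for s, t in graph.edges
        if new_id[s] != new_id[t]
    }
    return PathwayGraph(
        pathway_id=graph.pathway_id,
        title=graph.title,
        category=graph.category,
        nodes=dict(sorted(merged.items())),
        edges=edges,
    )


def downstream_significant_count(
    graph: PathwayGraph,
    node: str,
    significant: set[str] | frozenset[str],
    *,
    through_significant_only: bool = True,
) -> int:
    """Count distinct significant nodes downstream of ``node``.

    Depth-first search from ``node`` with an explicit stack and a visited set,
    so each node is counted once regardless of path multiplicity and the walk
    terminates on cycles.  With ``through_significant_only`` (the default)
    paths may only pass through significant intermediate nodes --
    non-significant nodes block propagation.  With it off, any directed path
    counts and the search traverses non-significant nodes too.

    The start node is never counted, even when it lies on a cycle back to
    itself.

    Raises
    ------
    KeyError
        If ``node`` is not in the graph.
    """
    if node not in graph.nodes:
        raise KeyError(f"node {node!r} not in pathway {graph.pathway_id}")
    adjacency = graph.adjacency()
    visited: set[str] = {node}
    stack: list[str] = [node]
    count = 0
    while stack:
        current = stack.pop()
        for child in adjacency[current]:
            if child in visited:
                continue
            if through_significant_only and child not in significant:
                continue
            visited.add(child)
            if child in significant:
                count += 1
            stack.append(child)
    return count
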