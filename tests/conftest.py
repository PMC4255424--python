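import numpy as np
import networkx as nx
import pytest

from prstool.graph_build import GeneNode, PathwayGraph
from prstool.expression import GeneStats


def make_graph(edges, nodes=None, pathway_id="test", category="signalling"):
    """PathwayGraph from an edge list of node-id strings (single-gene nodes)."""
    node_ids = set(nodes or [])
    for a, b in edges:
        node_ids |= {a, b}
    return PathwayGraph(
        pathway_id=pathway_id,
        title=pathway_id,
        category=category,
        nodes={
            nid: GeneNode(nid, frozenset({nid}), frozenset({nid}))
            for nid in node_ids
        },
        edges={tuple(e) for e in edges},
    )


def brute_force_downstream(graph, node, significant, *, through_significant_only=True):
    """Independent oracle: transitive closure via networkx on the induced subgraph.

    With significant-only propagation the subgraph is induced by {node} union
    the significant set; otherwise the full graph is used and reachable
    significant nodes are counted.
    """
    g = graph.to_networkx()
    if through_significant_only:
        keep = set(significant) | {node}
        g = g.subgraph(keep).copy()
    reachable = nx.descendants(g, node)
    return len(reachable & set(significant) - {node})


def reference_bh(p_values):
    """Independent Benjamini-Hochberg step-up, written long-hand."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    running_min = 1.0
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        candidate = p_values[i] * m / rank_from_end
        running_min = min(running_min, candidate)
        q[i] = min(running_min, 1.0)
    return q


def random_digraph(rng, max_nodes=12, density_range=(0.1, 0.5)):
    """Random digraph plus a random significant subset, for oracle checks."""
    n = int(rng.integers(2, max_nodes + 1))
    density = rng.uniform(*density_range)
    node_ids = [f"n{i}" for i in range(n)]
    edges = [
        (node_ids[a], node_ids[b])
        for a in range(n)
        for b in range(n)
        if a != b and rng.random() < density
    ]
    graph = make_graph(edges, nodes=node_ids)
    k = int(rng.integers(1, n + 1))
    significant = set(rng.choice(node_ids, size=k, replace=False).tolist())
    return graph, significant


def stats_for(sig_fc: dict[str, float], nonsig: list[str] = ()) -> list[GeneStats]:
    """GeneStats list: genes in ``sig_fc`` significant with that magnitude."""
    out = [
        GeneStats(g, f"probe_{g}", np.log2(fc), float(fc), 0.001, True)
        for g, fc in sig_fc.items()
    ]
    out += [GeneStats(g, f"probe_{g}", 0.0, 1.0, 0.9, False) for g in nonsig]
    return sorted(out, key=lambda s: s.gene_id)


@pytest.fixture(scope="session")
def demo_workspace(tmp_path_factory):
    """A small planted-signal workspace shared by integration tests."""
    from prstool.fixtures import FixtureSpec, write_demo_workspace

    out = tmp_path_factory.mktemp("workspace")
    spec = FixtureSpec(n_pathways=10, planted_pathway_index=0, seed=11)
    paths = write_demo_workspace(out, spec)
    return spec, paths
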