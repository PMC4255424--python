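"""Permutation-based significance of pathway scores, with FDR adjustment.

The null keeps the expression universe fixed and shuffles which gene carries
which (fold-change magnitude, significant) pair: a uniform random permutation
reassigns the observed pairs to gene IDs, the permuted values are mapped back
onto every pathway and the PRS recomputed.  Repeating n_perm times gives an
empirical p-value per pathway,

    p = #{permutations with permuted PRS >= observed PRS} / n_perm,

so p can be exactly zero; a ``smoothing`` flag switches to (count+1)/(n+1)
for users who want strictly positive p-values.  All pathways share the same
permutation stream, which preserves the cross-pathway correlation structure
of the null.  Totals T and F are invariant under permutation.

p-values are adjusted with the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .expression import GeneStats
from .graph_build import PathwayGraph
from .scoring import PathwayScore


@dataclass(frozen=True)
class PermutationResult:
    pathway_id: str
    observed_prs: float
    n_perm: int
    exceed_count: int
    p_value: float
    q_value: float
    significant_fdr: bool


def permute_gene_stats(
    stats: list[GeneStats], rng: np.random.Generator
) -> list[GeneStats]:
    """Reassign the (fc_magnitude, significant) pairs to genes uniformly.

    Gene IDs keep their order; the multiset of statistics is conserved, so
    the universe totals T and F are unchanged.  The donor's fold-change sign
    and p-value travel with the pair for consistency, though only magnitude
    and the significance flag enter the PRS.
    """
    if len(stats) < 2:
        raise ValueError("need at least 2 genes to permute")
    perm = rng.permutation(len(stats))
    return [
        GeneStats(
            gene_id=s.gene_id,
            probe_id=stats[j].probe_id,
            log2_fc=stats[j].log2_fc,
            fc_magnitude=stats[j].fc_magnitude,
            p_value=stats[j].p_value,
            significant=stats[j].significant,
        )
        for s, j in zip(stats, perm)
    ]


def empirical_p(observed: float, permuted_scores: np.ndarray, *, smoothing: bool = False) -> float:
    """p-value from a vector of permutation scores (>= comparison)."""
    count = int(np.count_nonzero(permuted_scores >= observed))
    n = len(permuted_scores)
    if smoothing:
        return (count + 1) / (n + 1)
    return count / n


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


class _CompactPathway:
    """Array view of one pathway for fast repeated PRS evaluation.

    Nodes are indexed 0..m-1; ``members[i]`` holds the universe indices of
    node i's expressed genes and ``adj[i]`` its child node indices.
    """

    __slots__ = ("pathway_id", "node_count", "members", "adj")

    def __init__(self, graph: PathwayGraph, gene_index: dict[str, int]):
        self.pathway_id = graph.pathway_id
        self.node_count = graph.node_count
        node_ids = sorted(graph.nodes)
        pos = {nid: i for i, nid in enumerate(node_ids)}
        self.members = [
            np.array(
                sorted(
                    gene_index[g]
                    for g in graph.nodes[nid].gene_ids
                    if g in gene_index
                ),
                dtype=np.intp,
            )
            for nid in node_ids
        ]
        adjacency = graph.adjacency()
        self.adj = [
            [pos[c] for c in adjacency[nid]] for nid in node_ids
        ]

    def prs(
        self,
        fc: np.ndarray,
        sig: np.ndarray,
        *,
        through_significant_only: bool = True,
    ) -> float:
        """PRS given per-universe-gene magnitude and significance arrays."""
        node_sig = np.zeros(self.node_count, dtype=bool)
        node_fc = np.empty(self.node_count)
        for i, members in enumerate(self.members):
            if members.size == 0:
                continue
            m_sig = sig[members]
            if m_sig.any():
                node_sig[i] = True
                node_fc[i] = fc[members[m_sig]].max()
        if not node_sig.any():
            return 0.0
        total = 0.0
        adj = self.adj
        for start in np.flatnonzero(node_sig):
            # DFS with a visited set: loops counted once, termination on cycles
            visited = {int(start)}
            stack = [int(start)]
            reach = 0
            while stack:
                for child in adj[stack.pop()]:
                    if child in visited:
                        continue
                    if node_sig[child]:
                        visited.add(child)
                        reach += 1
                        stack.append(child)
                    elif not through_significant_only:
                        visited.add(child)
                        stack.append(child)
            total += node_fc[start] * (1 + reach)
        return total / self.node_count


def permutation_pvalues(
    graphs: list[PathwayGraph],
    stats: list[GeneStats],
    observed: list[PathwayScore],
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
    *,
    fdr_threshold: float = 0.05,
    smoothing: bool = False,
    through_significant_only: bool = True,
    return_permuted_scores: bool = False,
):
    """Empirical p- and BH q-values for the observed PRS of every pathway.

    Parameters
    ----------
    graphs, stats, observed:
        Deduplicated pathway graphs, the gene universe statistics and the
        matching observed scores (same order as ``graphs``).
    n_perm:
        Number of fold-change permutations (typically 1000).
    rng:
        ``numpy.random.Generator`` or integer seed.
    return_permuted_scores:
        Also return the (n_perm, n_pathways) matrix of permuted PRS values.
    """
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    if len(graphs) != len(observed):
        raise ValueError("graphs and observed scores must align")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)

    genes = [s.gene_id for s in stats]
    gene_index = {g: i for i, g in enumerate(genes)}
    fc = np.array([s.fc_magnitude for s in stats])
    sig = np.array([s.significant for s in stats], dtype=bool)

    compact = [_CompactPathway(g, gene_index) for g in graphs]
    observed_prs = np.array([s.prs for s in observed])

    exceed = np.zeros(len(graphs), dtype=int)
    permuted = (
        np.empty((n_perm, len(graphs))) if return_permuted_scores else None
    )
    for k in range(n_perm):
        perm = rng.permutation(len(genes))
        fc_p, sig_p = fc[perm], sig[perm]
        for j, pw in enumerate(compact):
            score = pw.prs(
                fc_p, sig_p, through_significant_only=through_significant_only
            )
            if permuted is not None:
                permuted[k, j] = score
            if score >= observed_prs[j]:
                exceed[j] += 1

    if smoothing:
        p = (exceed + 1) / (n_perm + 1)
    else:
        p = exceed / n_perm
    q = bh_fdr(p)
    results = [
        PermutationResult(
            pathway_id=g.pathway_id,
            observed_prs=float(observed_prs[j]),
            n_perm=n_perm,
            exceed_count=int(exceed[j]),
            p_value=float(p[j]),
            q_value=float(q[j]),
            significant_fdr=bool(q[j] < fdr_threshold),
        )
        for j, g in enumerate(graphs)
    ]
    if return_permuted_scores:
        return results, permuted
    return results
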