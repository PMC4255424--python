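"""Pathway Regulation Score (PRS) and hypergeometric z-score.

The PRS of a pathway combines three ingredients:

* which nodes are significant (carry at least one differentially-expressed
  gene),
* their fold-change magnitude (the largest magnitude over significant member
  genes; the score is direction-free -- splitting pathways into up- and
  down-regulated halves is deliberately avoided),
* their topological weight: ``1 + downstream_significant_count``, i.e. one
  for the node itself plus the number of distinct significant nodes it points
  to directly or through other significant nodes.

    PRS_raw = sum over significant nodes of fc_magnitude * weight
    PRS     = PRS_raw / node_count        (normalized for pathway size)

The comparator z-score standardizes the observed DEG count f of a pathway
against its hypergeometric expectation given n pathway genes in a universe of
T genes with F significant:

    z = (f - n F/T) / sqrt( n (F/T) (1 - F/T) (1 - (n-1)/(T-1)) )

Both counts use deduplicated gene sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .expression import GeneStats, Universe
from .graph_build import PathwayGraph, downstream_significant_count


@dataclass(frozen=True)
class NodeAssessment:
    """Significance, magnitude and topological weight of one graph node."""

    node_id: str
    significant: bool
    fc_magnitude: float
    weight: int


@dataclass(frozen=True)
class PathwayScore:
    pathway_id: str
    title: str
    node_count: int
    n: int  #: pathway genes present in the expressed universe
    f: int  #: significant pathway genes
    prs_raw: float
    prs: float
    z_score: float  #: NaN when the hypergeometric variance is zero

    @property
    def z_defined(self) -> bool:
        return not math.isnan(self.z_score)


def assess_nodes(
    graph: PathwayGraph,
    stats: list[GeneStats] | dict[str, GeneStats],
    *,
    through_significant_only: bool = True,
) -> list[NodeAssessment]:
    """Assess every node of a deduplicated graph against gene statistics.

    A node is significant iff any of its member genes is significant; its
    magnitude is the maximum fold-change magnitude over significant members
    (1.0 if none); its weight is ``1 + downstream_significant_count`` for
    significant nodes and 0 otherwise.  Nodes with no expressed member genes
    are non-significant.
    """
    if isinstance(stats, list):
        stats = {s.gene_id: s for s in stats}
    significant_nodes: set[str] = set()
    magnitude: dict[str, float] = {}
    for nid in graph.nodes:
        fcs = [
            stats[g].fc_magnitude
            for g in graph.nodes[nid].gene_ids
            if g in stats and stats[g].significant
        ]
        if fcs:
            significant_nodes.add(nid)
            magnitude[nid] = max(fcs)
    out = []
    for nid in sorted(graph.nodes):
        if nid in significant_nodes:
            weight = 1 + downstream_significant_count(
                graph,
                nid,
                significant_nodes,
                through_significant_only=through_significant_only,
            )
            out.append(NodeAssessment(nid, True, magnitude[nid], weight))
        else:
            out.append(NodeAssessment(nid, False, 1.0, 0))
    return out


def compute_prs(
    assessments: list[NodeAssessment], node_count: int
) -> tuple[float, float]:
    """Return ``(prs_raw, prs)`` for one pathway.

    ``prs_raw`` sums fold-change magnitude times weight over significant
    nodes; ``prs`` divides by the deduplicated node count.
    """
    if node_count <= 0:
        raise ValueError("node_count must be positive")
    prs_raw = sum(a.fc_magnitude * a.weight for a in assessments if a.significant)
    return prs_raw, prs_raw / node_count


def compute_zscore(n: int, f: int, T: int, F: int) -> float:
    """Hypergeometric z-score of observing f significant among n pathway genes.

    Returns NaN when the variance term vanishes (F = 0, F = T or n = T), in
    which case the standardization is undefined; the pathway keeps its PRS.
    """
    if not (0 < n < T):
        raise ValueError(f"need 0 < n < T, got n={n}, T={T}")
    if not (0 <= f <= n and 0 <= F <= T):
        raise ValueError(f"invalid counts n={n}, f={f}, T={T}, F={F}")
    rate = F / T
    variance = n * rate * (1.0 - rate) * (1.0 - (n - 1) / (T - 1))
    if variance <= 0.0:
        return math.nan
    return (f - n * rate) / math.sqrt(variance)


def score_pathway(
    graph: PathwayGraph,
    stats: list[GeneStats] | dict[str, GeneStats],
    universe: Universe,
    *,
    through_significant_only: bool = True,
) -> PathwayScore:
    if isinstance(stats, list):
        stats = {s.gene_id: s for s in stats}
    assessments = assess_nodes(
        graph, stats, through_significant_only=through_significant_only
    )
    prs_raw, prs = compute_prs(assessments, graph.node_count)
    expressed = [g for g in graph.gene_ids() if g in stats]
    n = len(expressed)
    f = sum(stats[g].significant for g in expressed)
    if 0 < n < universe.T:
        z = compute_zscore(n, f, universe.T, universe.F)
    else:
        z = math.nan
    return PathwayScore(
        pathway_id=graph.pathway_id,
        title=graph.title,
        node_count=graph.node_count,
        n=n,
        f=f,
        prs_raw=prs_raw,
        prs=prs,
        z_score=z,
    )


def score_all(
    graphs: list[PathwayGraph],
    stats: list[GeneStats],
    universe: Universe,
    *,
    through_significant_only: bool = True,
) -> list[PathwayScore]:
    """Score every pathway; one :class:`PathwayScore` per graph."""
    stats_map = {s.gene_id: s for s in stats}
    return [
        score_pathway(
            g, stats_map, universe, through_significant_only=through_significant_only
        )
        for g in graphs
    ]


def rank_by_prs(scores: list[PathwayScore]) -> list[PathwayScore]:
    """Descending PRS; ties broken by pathway id for determinism."""
    return sorted(scores, key=lambda s: (-s.prs, s.pathway_id))


def rank_by_zscore(scores: list[PathwayScore]) -> list[PathwayScore]:
    """Descending z-score; pathways with undefined z placed last."""
    return sorted(
        scores,
        key=lambda s: (not s.z_defined, -(s.z_score if s.z_defined else 0.0), s.pathway_id),
    )
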