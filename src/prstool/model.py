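"""Model/Results interface tying the pipeline together.

:class:`PathwayEnrichment` is constructed from an expression matrix, a
probe-to-gene mapping and a set of parsed pathways; construction performs the
deterministic part of the analysis (graph building, deduplication, DEG
calling).  :meth:`PathwayEnrichment.fit` runs scoring and the permutation
null and returns a :class:`PathwayEnrichmentResults` carrying the per-pathway
estimates (PRS, z-score), their permutation p- and q-values, a ``summary()``
table and writers for the ranked output files.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import report
from .expression import (
    GeneStats,
    Universe,
    ExpressionMatrix,
    gene_stats,
    load_expression,
    load_mapping,
)
from .graph_build import EmptyPathwayError, PathwayGraph, build_graph
from .kgml_io import PathwayDefinition, parse_kgml_dir
from .scoring import PathwayScore, score_all
from .significance import PermutationResult, permutation_pvalues

logger = logging.getLogger(__name__)

PATHWAY_CLASSES = ("signalling", "metabolic", "both")


@dataclass
class StageCounts:
    """Bookkeeping of how many pathways survived each stage."""

    pathways_parsed: int = 0
    class_filtered: int = 0
    excluded_empty: int = 0
    pathways_scored: int = 0
    genes_mapped: int = 0
    n_deg: int = 0

    def reconciles(self) -> bool:
        return (
            self.pathways_scored
            == self.pathways_parsed - self.class_filtered - self.excluded_empty
        )


class PathwayEnrichment:
    """Topology-based pathway enrichment model.

    Parameters
    ----------
    matrix:
        Normalized expression values, control columns first.
    mapping:
        probe id -> gene id.
    definitions:
        Parsed KGML pathway definitions.
    fc_threshold, p_threshold:
        DEG calling thresholds (fold-change inclusive, p strict).
    pathway_classes:
        ``"signalling"``, ``"metabolic"`` or ``"both"``.
    log2_input:
        Whether expression values are on the log2 scale (RMA-style).
    through_significant_only:
        Whether downstream weighting requires significant intermediates
        (the default) or lets paths traverse non-significant nodes.
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        mapping: dict[str, str],
        definitions: list[PathwayDefinition],
        *,
        fc_threshold: float = 1.3,
        p_threshold: float = 0.05,
        pathway_classes: str = "both",
        log2_input: bool = True,
        through_significant_only: bool = True,
    ):
        if pathway_classes not in PATHWAY_CLASSES:
            raise ValueError(f"pathway_classes must be one of {PATHWAY_CLASSES}")
        self.fc_threshold = fc_threshold
        self.p_threshold = p_threshold
        self.pathway_classes = pathway_classes
        self.through_significant_only = through_significant_only
        self.counts = StageCounts(pathways_parsed=len(definitions))

        self.graphs: list[PathwayGraph] = []
        for defn in definitions:
            if pathway_classes != "both" and defn.category != pathway_classes:
                self.counts.class_filtered += 1
                continue
            try:
                self.graphs.append(build_graph(defn))
            except EmptyPathwayError as exc:
                logger.warning("excluding pathway: %s", exc)
                self.counts.excluded_empty += 1
        self.counts.pathways_scored = len(self.graphs)
        if not self.graphs:
            raise EmptyPathwayError("no scoreable pathway after filtering")

        self.stats, self.universe = gene_stats(
            matrix,
            mapping,
            fc_threshold=fc_threshold,
            p_threshold=p_threshold,
            log2_input=log2_input,
        )
        self.counts.genes_mapped = self.universe.T
        self.counts.n_deg = self.universe.F
        logger.info(
            "pathways: %d parsed, %d class-filtered, %d empty, %d scoreable; "
            "genes: %d mapped, %d DEGs",
            self.counts.pathways_parsed,
            self.counts.class_filtered,
            self.counts.excluded_empty,
            self.counts.pathways_scored,
            self.counts.genes_mapped,
            self.counts.n_deg,
        )

    @classmethod
    def from_files(
        cls,
        expression_path: str | os.PathLike,
        mapping_path: str | os.PathLike,
        kgml_dir: str | os.PathLike,
        n_control: int,
        n_test: int,
        **kwargs,
    ) -> "PathwayEnrichment":
        """Build the model from an expression table, mapping TSV and KGML dir."""
        matrix = load_expression(expression_path, n_control, n_test)
        mapping = load_mapping(mapping_path)
        definitions = parse_kgml_dir(kgml_dir)
        return cls(matrix, mapping, definitions, **kwargs)

    def kegg_color_url(self, pathway_id: str) -> str:
        """Colour-map URL for one pathway (significant genes red)."""
        for g in self.graphs:
            if g.pathway_id == pathway_id:
                return report.kegg_color_url(pathway_id, self.stats, g)
        raise KeyError(f"pathway {pathway_id!r} not among scored pathways")

    def fit(
        self,
        n_perm: int = 1000,
        seed: int | None = None,
        fdr_threshold: float = 0.05,
        *,
        smoothing: bool = False,
    ) -> "PathwayEnrichmentResults":
        """Score all pathways and assess significance by permutation."""
        scores = score_all(
            self.graphs,
            self.stats,
            self.universe,
            through_significant_only=self.through_significant_only,
        )
        perms = permutation_pvalues(
            self.graphs,
            self.stats,
            scores,
            n_perm=n_perm,
            rng=np.random.default_rng(seed),
            fdr_threshold=fdr_threshold,
            smoothing=smoothing,
            through_significant_only=self.through_significant_only,
        )
        return PathwayEnrichmentResults(
            model=self,
            scores=scores,
            perms=perms,
            n_perm=n_perm,
            seed=seed,
            fdr_threshold=fdr_threshold,
        )


class PathwayEnrichmentResults:
    """Fitted enrichment results: scores, significance and reporting."""

    def __init__(
        self,
        model: PathwayEnrichment,
        scores: list[PathwayScore],
        perms: list[PermutationResult],
        n_perm: int,
        seed: int | None,
        fdr_threshold: float,
    ):
        self.model = model
        self.scores = scores
        self.perms = perms
        self.n_perm = n_perm
        self.seed = seed
        self.fdr_threshold = fdr_threshold

    # -- tabular views ----------------------------------------------------

    def frame(self) -> pd.DataFrame:
        """All pathways with scores and significance, ranked by PRS."""
        perm_map = {p.pathway_id: p for p in self.perms}
        rows = []
        for s in self.scores:
            p = perm_map[s.pathway_id]
            rows.append(
                {
                    "pathway_id": s.pathway_id,
                    "title": s.title,
                    "node_count": s.node_count,
                    "n": s.n,
                    "f": s.f,
                    "prs_raw": s.prs_raw,
                    "prs": s.prs,
                    "z_score": s.z_score,
                    "p_value": p.p_value,
                    "q_value": p.q_value,
                    "significant_fdr": p.significant_fdr,
                }
            )
        df = pd.DataFrame(rows).sort_values(
            ["prs", "pathway_id"], ascending=[False, True]
        )
        df.insert(0, "rank", range(1, len(df) + 1))
        return df.reset_index(drop=True)

    def ranked_by_prs(self, fdr_filter: float | None = None):
        return report.build_result_rows(
            self.scores, self.perms, by="prs", fdr_filter=fdr_filter
        )

    def ranked_by_zscore(self, fdr_filter: float | None = None):
        return report.build_result_rows(
            self.scores, self.perms, by="zscore", fdr_filter=fdr_filter
        )

    def summary(self, top: int = 10) -> str:
        """Human-readable summary of the top pathways by PRS."""
        df = self.frame().head(top)
        lines = [
            "Pathway Regulation Score enrichment",
            f"  pathways scored: {len(self.scores)}   "
            f"universe: T={self.model.universe.T}, F={self.model.universe.F}",
            f"  thresholds: FC >= {self.model.fc_threshold}, "
            f"p < {self.model.p_threshold}; "
            f"permutations: {self.n_perm} (seed={self.seed}); "
            f"FDR < {self.fdr_threshold}",
            "",
        ]
        header = (
            f"{'rank':>4} {'pathway':<12} {'title':<34} {'prs':>10} "
            f"{'z':>8} {'p':>8} {'q':>8}"
        )
        lines.append(header)
        lines.append("-" * len(header))
        for _, r in df.iterrows():
            z = "NA" if math.isnan(r.z_score) else f"{r.z_score:8.3f}"
            lines.append(
                f"{int(r['rank']):>4} {r.pathway_id:<12} {r.title[:34]:<34} "
                f"{r.prs:>10.6f} {z:>8} {r.p_value:>8.4f} {r.q_value:>8.4f}"
            )
        return "\n".join(lines)

    # -- persistence ------------------------------------------------------

    def metadata(self) -> dict:
        return {
            "fc_threshold": self.model.fc_threshold,
            "p_threshold": self.model.p_threshold,
            "pathway_classes": self.model.pathway_classes,
            "n_perm": self.n_perm,
            "fdr_threshold": self.fdr_threshold,
            "seed": self.seed,
            "universe_T": self.model.universe.T,
            "universe_F": self.model.universe.F,
            "stage_counts": self.model.counts.__dict__,
        }

    def save(
        self,
        out_dir: str | os.PathLike,
        *,
        fdr_filter: float | None = None,
        xlsx: bool = True,
    ) -> dict:
        """Write ranked CSV/XLSX tables and the JSON run state."""
        return report.write_ranked_tables(
            self.scores,
            self.perms,
            out_dir,
            metadata=self.metadata(),
            fdr_filter=fdr_filter,
            xlsx=xlsx,
        )

    def kegg_color_url(self, pathway_id: str) -> str:
        """Colour-map URL for one scored pathway (significant genes red)."""
        return self.model.kegg_color_url(pathway_id)
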