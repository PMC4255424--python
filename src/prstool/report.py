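"""Ranked result tables and KEGG colour-map URLs.

Two tables are written per run -- one ranked by PRS, one by z-score -- as CSV
(canonical) with an XLSX mirror, plus a JSON run-state file holding the run
metadata (thresholds, permutation count, seed, tool version) and the full
result rows.  Scores are printed with 6 decimal places; an undefined z-score
prints as ``NA``.

The KEGG visualization support constructs (but never fetches) a deterministic
URL for the public pathway colour-mapping endpoint, marking significant genes
red and the remaining expressed genes green.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .expression import GeneStats
from .graph_build import PathwayGraph
from .scoring import PathwayScore, rank_by_prs, rank_by_zscore
from .significance import PermutationResult

_SCORE_FMT = "{:.6f}"

KEGG_SHOW_PATHWAY = "https://www.kegg.jp/kegg-bin/show_pathway"


@dataclass(frozen=True)
class ResultRow:
    rank: int
    pathway_id: str
    title: str
    prs: float
    z_score: float  # NaN when undefined
    p_value: float
    q_value: float
    n: int
    f: int


def _fmt(x: float) -> str:
    return "NA" if math.isnan(x) else _SCORE_FMT.format(x)


def build_result_rows(
    scores: list[PathwayScore],
    perms: list[PermutationResult] | None,
    *,
    by: str = "prs",
    fdr_filter: float | None = None,
) -> list[ResultRow]:
    """Rank pathways and attach permutation p/q-values.

    ``by`` is ``"prs"`` or ``"zscore"``; with ``fdr_filter`` set, only rows
    with q-value strictly below the threshold are retained (ranks are then
    re-numbered 1..K over the retained rows).
    """
    if by == "prs":
        ranked = rank_by_prs(scores)
    elif by == "zscore":
        ranked = rank_by_zscore(scores)
    else:
        raise ValueError(f"unknown ranking {by!r}")
    perm_map = {p.pathway_id: p for p in (perms or [])}
    rows: list[ResultRow] = []
    for score in ranked:
        perm = perm_map.get(score.pathway_id)
        p = perm.p_value if perm else math.nan
        q = perm.q_value if perm else math.nan
        if fdr_filter is not None and not (q < fdr_filter):
            continue
        rows.append(
            ResultRow(
                rank=len(rows) + 1,
                pathway_id=score.pathway_id,
                title=score.title,
                prs=score.prs,
                z_score=score.z_score,
                p_value=p,
                q_value=q,
                n=score.n,
                f=score.f,
            )
        )
    return rows


def rows_to_frame(rows: list[ResultRow]) -> pd.DataFrame:
    """Result rows as a DataFrame with scores formatted to 6 decimals."""
    return pd.DataFrame(
        {
            "rank": [r.rank for r in rows],
            "pathway_id": [r.pathway_id for r in rows],
            "title": [r.title for r in rows],
            "prs": [_fmt(r.prs) for r in rows],
            "z_score": [_fmt(r.z_score) for r in rows],
            "p_value": [_fmt(r.p_value) for r in rows],
            "q_value": [_fmt(r.q_value) for r in rows],
            "n": [r.n for r in rows],
            "f": [r.f for r in rows],
        }
    )


def write_ranked_tables(
    scores: list[PathwayScore],
    perms: list[PermutationResult] | None,
    out_dir: str | os.PathLike,
    metadata: dict | None = None,
    *,
    fdr_filter: float | None = None,
    xlsx: bool = True,
) -> dict[str, Path]:
    """Write PRS- and z-score-ranked tables plus the JSON run state.

    Returns a dict of logical name -> written path.
    """
    if not scores:
        raise ValueError("no scored pathways to report")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    rows_by = {}
    for by, stem in (("prs", "prs_ranking"), ("zscore", "zscore_ranking")):
        rows = build_result_rows(scores, perms, by=by, fdr_filter=fdr_filter)
        rows_by[by] = rows
        frame = rows_to_frame(rows)
        csv_path = out_dir / f"{stem}.csv"
        frame.to_csv(csv_path, index=False)
        written[f"{by}_csv"] = csv_path
        if xlsx:
            xlsx_path = out_dir / f"{stem}.xlsx"
            frame.to_excel(xlsx_path, index=False)
            written[f"{by}_xlsx"] = xlsx_path
    state = {
        "tool": "prstool",
        "version": __version__,
        "metadata": metadata or {},
        "prs_ranking": [r.__dict__ for r in rows_by["prs"]],
        "zscore_ranking": [r.__dict__ for r in rows_by["zscore"]],
    }
    state_path = out_dir / "run_state.json"
    with open(state_path, "w") as fh:
        json.dump(state, fh, indent=2, allow_nan=True, default=str)
    written["run_state"] = state_path
    return written


def read_ranked_csv(path: str | os.PathLike) -> pd.DataFrame:
    """Read a ranking CSV back, keeping scores as their printed strings."""
    return pd.read_csv(path, dtype=str)


def kegg_color_url(
    pathway_id: str,
    stats: list[GeneStats] | dict[str, GeneStats],
    graph: PathwayGraph | None = None,
    *,
    organism_code: str | None = None,
    significant_color: str = "red",
    background_color: str = "green",
) -> str:
    """Build the KEGG colour-mapping URL for one pathway.

    Every expressed gene (restricted to the pathway's genes when ``graph`` is
    given) is encoded with a background colour: ``significant_color`` for
    DEGs, ``background_color`` otherwise.  Pure string assembly, deterministic
    for identical inputs; no network call is made.
    """
    if isinstance(stats, list):
        stats = {s.gene_id: s for s in stats}
    if organism_code is None:
        organism_code = "".join(c for c in pathway_id if c.isalpha())
    if graph is not None:
        genes = sorted(g for g in graph.gene_ids() if g in stats)
    else:
        genes = sorted(stats)
    if not genes:
        raise ValueError(f"{pathway_id}: no expressed genes to colour")
    prefix = f"{organism_code}:" if organism_code else ""
    tokens = [
        f"{prefix}{g}+{significant_color if stats[g].significant else background_color}"
        for g in genes
    ]
    # multi_query rows are CRLF-separated "gene bgcolor" pairs ('+' = space)
    return (
        f"{KEGG_SHOW_PATHWAY}?map={pathway_id}&multi_query="
        + "%0d%0a".join(tokens)
    )
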