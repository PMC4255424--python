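"""Loading expression tables, probe-to-gene collapse and DEG calling.

The expected input is an RMA-style normalized table: first column probe ID,
then the control replicate columns followed by the test replicate columns,
values on the log2 scale.  No normalization is performed here -- upstream
preprocessing is the user's job.

Per probe a Welch two-sample two-sided t-test and a log2 fold-change are
computed; probes are then collapsed to genes by keeping the probe with the
smallest p-value (ties broken by larger \\|log2 FC\\|, then probe ID).  A gene
is called differentially expressed when its fold-change magnitude meets the
threshold (inclusive) and its p-value is below the p threshold (strict).
"""

from __future__ import annotations

import logging
import os
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


class ExpressionFormatError(Exception):
    """Non-numeric cells, bad column counts, unreadable tables."""


@dataclass
class ExpressionMatrix:
    """Probes x samples matrix of normalized intensities.

    Sample order is control columns first, then test columns.
    """

    probe_ids: list[str]
    values: np.ndarray
    n_control: int
    n_test: int

    def __post_init__(self) -> None:
        if self.n_control < 2 or self.n_test < 2:
            raise ExpressionFormatError(
                "need at least 2 replicates per group "
                f"(got {self.n_control} control, {self.n_test} test)"
            )
        if self.values.shape != (len(self.probe_ids), self.n_control + self.n_test):
            raise ExpressionFormatError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x "
                f"{self.n_control + self.n_test} samples"
            )

    @property
    def control(self) -> np.ndarray:
        return self.values[:, : self.n_control]

    @property
    def test(self) -> np.ndarray:
        return self.values[:, self.n_control :]


@dataclass(frozen=True)
class GeneStats:
    """Differential-expression summary for one gene (best probe)."""

    gene_id: str
    probe_id: str
    log2_fc: float
    fc_magnitude: float
    p_value: float
    significant: bool


@dataclass(frozen=True)
class Universe:
    """Array-wide totals shared by the z-score and the permutation null.

    T is the number of expressed, gene-mapped genes; F the number of those
    called significant.
    """

    T: int
    F: int

    def __post_init__(self) -> None:
        if not (0 <= self.F <= self.T) or self.T <= 0:
            raise ValueError(f"invalid universe T={self.T}, F={self.F}")


def _read_table(path: Path) -> pd.DataFrame:
    suffix = path.suffix.lower()
    if suffix in {".xlsx", ".xlsm"}:
        return pd.read_excel(path, sheet_name=0, engine="openpyxl")
    sep = "\t" if suffix in {".tsv", ".txt"} else ","
    return pd.read_csv(path, sep=sep)


def load_expression(
    path: str | os.PathLike, n_control: int, n_test: int
) -> ExpressionMatrix:
    """Load an expression table from XLSX (first sheet), CSV or TSV.

    One header row; column 1 holds probe IDs, the remaining columns the
    control then test replicate values.  Blank cells become NaN (the probe is
    later dropped); text in a value cell is an error naming the probe and
    column.
    """
    path = Path(path)
    df = _read_table(path)
    if df.shape[1] < 1 + n_control + n_test:
        raise ExpressionFormatError(
            f"{path}: {df.shape[1] - 1} value columns, "
            f"need {n_control + n_test} (n_control={n_control}, n_test={n_test})"
        )
    if df.shape[1] > 1 + n_control + n_test:
        logger.warning(
            "%s: %d extra columns beyond n_control+n_test ignored",
            path,
            df.shape[1] - 1 - n_control - n_test,
        )
    probe_ids = df.iloc[:, 0].astype(str).tolist()
    value_df = df.iloc[:, 1 : 1 + n_control + n_test]
    columns = []
    for col in value_df.columns:
        raw = value_df[col]
        coerced = pd.to_numeric(raw, errors="coerce")
        bad = coerced.isna() & raw.notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ExpressionFormatError(
                f"{path}: non-numeric value {raw.iloc[row]!r} in column "
                f"{col!r}, probe {probe_ids[row]!r}"
            )
        columns.append(coerced.to_numpy(dtype=float))
    values = np.column_stack(columns)
    return ExpressionMatrix(probe_ids, values, n_control, n_test)


def load_mapping(path: str | os.PathLike) -> dict[str, str]:
    """Load a two-column probe -> gene TSV into a dict.

    A header row is auto-detected by a non-numeric second field on the first
    line.  Duplicate probe rows keep the first gene seen (a probe maps to at
    most one gene); later conflicting rows are logged.
    """
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t") if "\t" in line else line.split(",")
            if len(fields) < 2:
                raise ExpressionFormatError(
                    f"{path}: line {i + 1} has fewer than 2 columns"
                )
            probe, gene = fields[0].strip(), fields[1].strip()
            if i == 0 and not gene.replace(".", "").isdigit():
                continue  # header row
            if probe in mapping and mapping[probe] != gene:
                logger.warning(
                    "%s: probe %s maps to both %s and %s; keeping the first",
                    path, probe, mapping[probe], gene,
                )
                continue
            mapping[probe] = gene
    return mapping


def _welch_pvalues(control: np.ndarray, test: np.ndarray) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # 0/0 for zero-variance probes
        result = sps.ttest_ind(test, control, axis=1, equal_var=False)
    p = np.asarray(result.pvalue, dtype=float)
    # zero variance in both groups with identical means: t undefined -> p = 1
    undefined = np.isnan(p)
    if undefined.any():
        logger.warning(
            "%d probes with undefined t statistic; p set to 1.0", int(undefined.sum())
        )
        p[undefined] = 1.0
    return p


def gene_stats(
    matrix: ExpressionMatrix,
    mapping: dict[str, str],
    fc_threshold: float = 1.3,
    p_threshold: float = 0.05,
    *,
    log2_input: bool = True,
) -> tuple[list[GeneStats], Universe]:
    """Collapse probes to genes and call differential expression.

    Parameters
    ----------
    fc_threshold:
        Minimum fold-change magnitude (ratio >= 1), inclusive.
    p_threshold:
        Welch t-test p-value cut-off, strict.
    log2_input:
        If True (RMA-style data) the fold-change is ``2**(mean_test -
        mean_control)``; if False values are on the linear scale and the
        fold-change is the ratio of group means.

    Returns
    -------
    (stats, universe):
        Per-gene statistics sorted by gene ID, and the array-wide totals
        ``Universe(T, F)`` over mapped genes.
    """
    if fc_threshold < 1:
        raise ValueError(f"fc_threshold must be >= 1, got {fc_threshold}")
    if not (0 < p_threshold <= 1):
        raise ValueError(f"p_threshold must be in (0, 1], got {p_threshold}")

    complete = ~np.isnan(matrix.values).any(axis=1)
    if not complete.all():
        logger.warning(
            "dropping %d probes with missing values", int((~complete).sum())
        )
    values = matrix.values[complete]
    probe_ids = [p for p, ok in zip(matrix.probe_ids, complete) if ok]
    control = values[:, : matrix.n_control]
    test = values[:, matrix.n_control :]

    if log2_input:
        log2_fc = test.mean(axis=1) - control.mean(axis=1)
    else:
        mc, mt = control.mean(axis=1), test.mean(axis=1)
        if (mc <= 0).any() or (mt <= 0).any():
            raise ExpressionFormatError(
                "linear-scale input requires positive group means"
            )
        log2_fc = np.log2(mt / mc)
    p_values = _welch_pvalues(control, test)

    by_gene: dict[str, tuple[float, float, str, int]] = {}
    for i, probe in enumerate(probe_ids):
        gene = mapping.get(probe)
        if gene is None:
            continue
        # best probe: smallest p, then largest |log2 FC|, then probe ID
        key = (p_values[i], -abs(log2_fc[i]), probe)
        if gene not in by_gene or key < by_gene[gene][:3]:
            by_gene[gene] = (p_values[i], -abs(log2_fc[i]), probe, i)

    stats_out: list[GeneStats] = []
    n_sig = 0
    for gene in sorted(by_gene):
        p, _, probe, i = by_gene[gene]
        fc_magnitude = float(2.0 ** abs(log2_fc[i]))
        significant = bool(fc_magnitude >= fc_threshold and p < p_threshold)
        n_sig += int(significant)
        stats_out.append(
            GeneStats(
                gene_id=gene,
                probe_id=probe,
                log2_fc=float(log2_fc[i]),
                fc_magnitude=fc_magnitude,
                p_value=float(p),
                significant=bool(significant),
            )
        )
    if not stats_out:
        raise ExpressionFormatError("no probe mapped to any gene")
    return stats_out, Universe(T=len(stats_out), F=n_sig)
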