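"""Phage-host co-occurrence across metagenomic samples.

A phage can only thrive where its host is present, so phage and host
abundance profiles across samples should co-vary.  Profiles are compared
with Pearson correlation under two guards against the spurious
correlations that sparse profiles invite: samples where either member is
absent (abundance exactly 0) are excluded from each pairwise comparison,
and a correlation is only reported when more than six samples survive
that exclusion (>6, i.e. at least 7).  Pairs failing the rule are
no-evidence, distinct from any low correlation.

Correlations are computed on raw abundances by default; a log transform
is available but off by default.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .scoretable import ScoreTable

__all__ = [
    "read_abundance_tsv",
    "write_abundance_tsv",
    "pair_correlation",
    "abundance_scores",
    "AbundanceFormatError",
    "MIN_SHARED_SAMPLES",
]

MIN_SHARED_SAMPLES = 7  # ">6 samples with non-zero values"


class AbundanceFormatError(ValueError):
    """Raised for malformed abundance tables."""


def read_abundance_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """Read a genome x sample abundance matrix.

    First column holds genome ids, the header row sample ids.  Missing
    cells read as 0; negative or non-numeric entries and duplicate row
    ids are errors.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise AbundanceFormatError(f"duplicate genome id {dup!r} in {path}")
    values = np.zeros(raw.shape, dtype=float)
    for i, rid in enumerate(raw.index):
        for j, cid in enumerate(raw.columns):
            cell = raw.iat[i, j].strip()
            if cell == "":
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise AbundanceFormatError(
                    f"{path}: non-numeric abundance {cell!r} at row {rid!r}, column {cid!r}"
                ) from None
    if (values < 0).any():
        i, j = np.argwhere(values < 0)[0]
        raise AbundanceFormatError(
            f"{path}: negative abundance at row {raw.index[i]!r}, column {raw.columns[j]!r}"
        )
    return pd.DataFrame(values, index=raw.index, columns=raw.columns)


def write_abundance_tsv(matrix: pd.DataFrame, path: str | os.PathLike) -> None:
    out = matrix.copy()
    out.index.name = "genome"
    out.to_csv(path, sep="\t")


def pair_correlation(
    phage_row: np.ndarray,
    host_row: np.ndarray,
    min_shared: int = MIN_SHARED_SAMPLES,
    log_transform: bool = False,
) -> float | None:
    """Pearson correlation over mutually non-zero samples, or None.

    None (no evidence) when fewer than ``min_shared`` samples have both
    members present, or when either surviving vector is constant.
    """
    x = np.asarray(phage_row, dtype=float)
    y = np.asarray(host_row, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"profile length mismatch: {x.shape} vs {y.shape}")
    mask = (x > 0) & (y > 0)
    if int(mask.sum()) < min_shared:
        return None
    xs, ys = x[mask], y[mask]
    if log_transform:
        xs, ys = np.log(xs), np.log(ys)
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return None
    return float(np.corrcoef(xs, ys)[0, 1])


def abundance_scores(
    phage_matrix: pd.DataFrame,
    host_matrix: pd.DataFrame,
    min_shared: int = MIN_SHARED_SAMPLES,
    log_transform: bool = False,
) -> ScoreTable:
    """Pairwise co-occurrence correlations as a ScoreTable.

    Both matrices must cover the same samples (order-insensitive); pairs
    failing the shared-sample rule are no-evidence (NaN).
    """
    if set(phage_matrix.columns) != set(host_matrix.columns):
        raise ValueError("phage and host matrices must share the same sample ids")
    host_matrix = host_matrix[phage_matrix.columns]
    pvals = phage_matrix.to_numpy(dtype=float)
    hvals = host_matrix.to_numpy(dtype=float)
    table = np.full((pvals.shape[0], hvals.shape[0]), np.nan)
    for i in range(pvals.shape[0]):
        for j in range(hvals.shape[0]):
            r = pair_correlation(pvals[i], hvals[j], min_shared, log_transform)
            if r is not None:
                table[i, j] = r
    return ScoreTable(
        scores=pd.DataFrame(table, index=phage_matrix.index, columns=host_matrix.index),
        higher_is_better=True,
        name="abundance_pearson",
    )
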