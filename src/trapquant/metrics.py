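"""Acquisition-comparison metrics: detection counts, replicate
correlation, MaxSD, missingness, intensity spread, cross-acquisition
fold-change correlation.

These are the descriptive statistics used to compare DDA and DIA arms
of the same experiment: how many proteins each acquisition detects, how
reproducible replicate intensities are (pairwise R^2 of log2 raw
intensities), how consistent light/heavy ratios are across replicates
(MaxSD: the larger of the two time points' replicate standard
deviations), and how well per-gene fold-changes agree between
acquisitions.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd

from .quantify import ProteinQuantTable

logger = logging.getLogger(__name__)


def pearson_r2(x, y) -> float:
    """Squared Pearson correlation over pairwise-complete values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    both = ~np.isnan(x) & ~np.isnan(y)
    if both.sum() < 3:
        raise ValueError("need >= 3 pairwise-complete values")
    xs, ys = x[both], y[both]
    vx, vy = xs.var(), ys.var()
    if vx == 0.0 or vy == 0.0:
        return np.nan
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


def replicate_correlation(
    matrix: pd.DataFrame, replicate_columns: list[str]
) -> dict:
    """Pairwise R^2 of log2 raw intensities between replicate samples.

    Each pair uses genes non-missing in both replicates; pairs sharing
    fewer than 3 genes are skipped with a warning. Returns mean, SD
    (ddof=1) and the per-pair list.
    """
    if len(replicate_columns) < 2:
        raise ValueError("need >= 2 replicate columns")
    pairs = []
    for c1, c2 in combinations(replicate_columns, 2):
        try:
            r2 = pearson_r2(matrix[c1], matrix[c2])
        except ValueError:
            logger.warning("pair (%s, %s) skipped: <3 shared genes", c1, c2)
            continue
        pairs.append({"a": c1, "b": c2, "r2": r2})
    r2s = np.array([p["r2"] for p in pairs], dtype=float)
    return {
        "mean_r2": float(np.mean(r2s)) if len(r2s) else np.nan,
        "sd_r2": float(np.std(r2s, ddof=1)) if len(r2s) > 1 else np.nan,
        "pairs": pairs,
    }


def max_replicate_sd(
    pq: ProteinQuantTable, log_scale: bool = False, min_reps: int = 2
) -> pd.Series:
    """Per-gene MaxSD: the larger replicate SD of the two time points.

    SDs use the n-1 denominator over non-missing ratios; a time point
    with fewer than ``min_reps`` values contributes nothing, and a gene
    with no usable time point gets NaN. Computed on linear light/heavy
    ratios by default (``log_scale=True`` switches to log2 ratios).
    """
    ratios = np.log2(pq.ratios) if log_scale else pq.ratios
    per_tp = []
    for tp in pq.timepoints():
        block = ratios[tp]
        sd = block.std(axis=1, ddof=1)
        sd = sd.where(block.notna().sum(axis=1) >= min_reps)
        per_tp.append(sd)
    out = pd.concat(per_tp, axis=1).max(axis=1)
    out.name = "max_replicate_sd"
    return out


def detection_and_missingness_summary(
    matrix: pd.DataFrame, condition_columns: dict[str, list[str]]
) -> dict:
    """Detection counts, missingness and spread per condition.

    ``condition_columns`` maps a condition label to its replicate sample
    columns. Per condition: mean and SD (ddof=1) of per-replicate
    detected (non-missing) feature counts, percent missing cells, and
    the per-sample log2-intensity IQR (matrix assumed log2).
    """
    out = {}
    for cond, cols in condition_columns.items():
        block = matrix[cols]
        counts = block.notna().sum(axis=0)
        analyzable = block.notna().any(axis=1)
        sub = block.loc[analyzable]
        n_cells = sub.size
        missing_pct = 100.0 * float(sub.isna().to_numpy().sum()) / n_cells if n_cells else np.nan
        iqr = (block.quantile(0.75) - block.quantile(0.25)).astype(float)
        out[cond] = {
            "detected_mean": float(counts.mean()),
            "detected_sd": float(counts.std(ddof=1)) if len(cols) > 1 else np.nan,
            "detected_per_replicate": {c: int(v) for c, v in counts.items()},
            "missing_pct": missing_pct,
            "log2_iqr_per_sample": {c: float(v) for c, v in iqr.items()},
        }
    return out


def cross_acquisition_fc_correlation(
    fc_a: pd.Series, fc_b: pd.Series, genes=None
) -> float:
    """R^2 of per-gene log2 fold-changes between two acquisitions.

    The correlation runs over the gene intersection (optionally further
    restricted to ``genes``) with non-missing values on both sides.
    """
    shared = fc_a.index.intersection(fc_b.index)
    if genes is not None:
        shared = shared.intersection(pd.Index(genes))
    if len(shared) == 0:
        raise ValueError("no shared genes between the fold-change vectors")
    return pearson_r2(fc_a.loc[shared].to_numpy(), fc_b.loc[shared].to_numpy())
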