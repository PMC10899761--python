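"""Differential RNA-association and crosslink-enrichment statistics.

Two classifications are produced:

* crosslink enrichment — a protein is treated as genuinely RNA-bound if
  it is detected only in UV-crosslinked samples, or significantly more
  abundant there (Welch t-test on mean-normalized log2 protein
  intensities, BH FDR < 0.05 and linear fold-change > 1.5);
* differential RNA association between the 10 min and 1 h arsenite time
  points — Welch t-test on log2 light/heavy ratios with BH correction,
  with the primary significance call requiring p < 0.05 AND a log2
  fold-change beyond the dataset's own 10th/90th percentiles.

Welch (unequal-variance) is the default t-test; at n = 3 per group the
pooled test's equal-variance assumption is untestable. Fold changes are
differences of log2 means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError
from .quantify import ProteinQuantTable

logger = logging.getLogger(__name__)

_TINY_P = np.nextafter(0.0, 1.0)


# ----------------------------------------------------------------------
def welch_t_test(
    group_a, group_b, equal_var: bool = False
) -> tuple[float, float, float]:
    """Two-sided t-test; Welch-Satterthwaite df unless ``equal_var``.

    Returns (t, df, p). Degenerate cases: fewer than two values in
    either group -> (nan, nan, nan); both groups constant with equal
    means -> p = 1; constant with different means -> smallest
    representable positive p.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        return (np.nan, np.nan, np.nan)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return (0.0, float(len(a) + len(b) - 2), 1.0)
        sign = np.sign(a.mean() - b.mean())
        return (sign * np.inf, float(len(a) + len(b) - 2), _TINY_P)
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    df = getattr(res, "df", np.nan)
    if np.isnan(df):  # older scipy: recompute Welch df
        na, nb = len(a), len(b)
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
    return (float(res.statistic), float(df), float(res.pvalue))


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up adjusted q-values; missing p in -> missing q out.

    q_(i) = min_{j >= i} (p_(j) * m / j), capped at 1, with m the count
    of non-missing p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    obs = np.flatnonzero(~np.isnan(p))
    m = len(obs)
    if m == 0:
        return q
    order = obs[np.argsort(p[obs], kind="mergesort")]
    ranked = p[order] * m / np.arange(1, m + 1)
    q[order] = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    return q


def percentile_thresholds(log2fc, min_n: int = 10) -> tuple[float, float]:
    """10th and 90th percentile of log2 fold-changes (type-7 estimator)."""
    x = np.asarray(log2fc, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < min_n:
        raise InsufficientDataError(
            f"percentile thresholds need >= {min_n} values, got {len(x)}"
        )
    p10, p90 = np.percentile(x, [10.0, 90.0], method="linear")
    return (float(p10), float(p90))


# ----------------------------------------------------------------------
@dataclass
class EnrichmentConfig:
    alpha: float = 0.05
    min_fc: float = 1.5
    equal_var: bool = False


def crosslink_enrichment(
    cl_matrix: pd.DataFrame,
    noncl_matrix: pd.DataFrame,
    config: EnrichmentConfig | None = None,
) -> pd.DataFrame:
    """Classify proteins as crosslink-enriched (genuinely RNA-bound).

    Inputs are protein-level log2 intensity frames (genes x samples,
    mean-normalized upstream); the crosslinked and non-crosslinked sides
    each contribute their samples as independent observations. A gene
    detected in >= 1 crosslinked sample and no non-crosslinked sample is
    enriched by exclusivity; otherwise it is enriched iff BH q < alpha
    and linear fold-change > min_fc. Genes absent from both sides are
    omitted.

    Returns a frame indexed by gene: n_cl, n_noncl, mean_log2fc, fc,
    p_value, q_value, exclusive_to_cl, enriched.
    """
    config = config or EnrichmentConfig()
    genes = cl_matrix.index.union(noncl_matrix.index)
    cl = cl_matrix.reindex(genes)
    noncl = noncl_matrix.reindex(genes)
    n_cl = cl.notna().sum(axis=1)
    n_noncl = noncl.notna().sum(axis=1)
    present = (n_cl + n_noncl) > 0
    genes = genes[present]
    cl, noncl = cl.loc[genes], noncl.loc[genes]
    n_cl, n_noncl = n_cl[genes], n_noncl[genes]

    exclusive = (n_cl >= 1) & (n_noncl == 0)
    mean_diff = cl.mean(axis=1) - noncl.mean(axis=1)

    pvals = pd.Series(np.nan, index=genes)
    for g in genes:
        if exclusive[g]:
            continue
        _, _, p = welch_t_test(
            cl.loc[g].to_numpy(), noncl.loc[g].to_numpy(), config.equal_var
        )
        pvals[g] = p
    qvals = pd.Series(benjamini_hochberg(pvals.to_numpy()), index=genes)

    fc = np.power(2.0, mean_diff)
    enriched = exclusive | (
        (qvals < config.alpha) & (fc > config.min_fc)
    ).fillna(False)
    return pd.DataFrame(
        {
            "n_cl": n_cl,
            "n_noncl": n_noncl,
            "mean_log2fc": mean_diff,
            "fc": fc,
            "p_value": pvals,
            "q_value": qvals,
            "exclusive_to_cl": exclusive,
            "enriched": enriched,
        }
    ).rename_axis("gene")


# ----------------------------------------------------------------------
@dataclass
class DifferentialConfig:
    alpha: float = 0.05
    bh_alpha: float = 0.05
    min_reps: int = 2
    percentiles: tuple[float, float] = (10.0, 90.0)
    equal_var: bool = False


def differential_association(
    pq: ProteinQuantTable,
    config: DifferentialConfig | None = None,
    enrichment: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Differential RNA association between the two time points.

    Genes with fewer than ``min_reps`` non-missing ratios at either time
    point are excluded from testing (their dynamics are not reliably
    measured in either acquisition). For the rest, a two-sided Welch
    t-test compares log2 ratios between time points; BH correction runs
    over tested genes; the 10th/90th percentile thresholds are computed
    on the log2FC of the tested genes. Primary significance requires
    p < alpha and log2FC beyond a percentile threshold; BH significance
    requires q < bh_alpha. If an enrichment table is supplied, its
    ``enriched`` flag is joined as ``crosslink_enriched`` and the
    headline call ``significant_rbp`` intersects the two.

    Returns a frame indexed by gene, sorted by gene; attrs carry
    thresholds and counts.
    """
    config = config or DifferentialConfig()
    tps = pq.timepoints()
    if len(tps) != 2:
        raise InsufficientDataError(f"need exactly two time points, have {tps}")
    tp_a, tp_b = tps  # sorted: t10min, t1h

    log2 = np.log2(pq.ratios)
    a, b = log2[tp_a], log2[tp_b]
    n_a, n_b = a.notna().sum(axis=1), b.notna().sum(axis=1)
    testable = (n_a >= config.min_reps) & (n_b >= config.min_reps)
    excluded = int((~testable).sum())

    genes = pq.genes[testable]
    mean_a, mean_b = a.loc[genes].mean(axis=1), b.loc[genes].mean(axis=1)
    log2fc = mean_b - mean_a  # 1 h minus 10 min

    pvals = pd.Series(
        [
            welch_t_test(
                b.loc[g].to_numpy(), a.loc[g].to_numpy(), config.equal_var
            )[2]
            for g in genes
        ],
        index=genes,
    )
    qvals = pd.Series(benjamini_hochberg(pvals.to_numpy()), index=genes)

    try:
        p_lo, p_hi = percentile_thresholds(log2fc.to_numpy())
    except InsufficientDataError:
        logger.warning("fewer than 10 testable genes: percentile gate unavailable")
        p_lo = p_hi = np.nan

    if np.isnan(p_lo):
        primary = pd.Series(False, index=genes)
    else:
        primary = (pvals < config.alpha) & ((log2fc > p_hi) | (log2fc < p_lo))
    sig_bh = qvals < config.bh_alpha

    res = pd.DataFrame(
        {
            "mean_log2_ratio_t10": mean_a,
            "mean_log2_ratio_t1h": mean_b,
            "log2fc": log2fc,
            "p_value": pvals,
            "q_value": qvals,
            "significant_primary": primary.fillna(False),
            "significant_bh": sig_bh.fillna(False),
        }
    ).rename_axis("gene")
    if enrichment is not None:
        res["crosslink_enriched"] = (
            enrichment["enriched"].reindex(res.index, fill_value=False).astype(bool)
        )
        res["significant_rbp"] = res["significant_primary"] & res["crosslink_enriched"]
    res = res.sort_index()
    res.attrs.update(
        {
            "p10": p_lo,
            "p90": p_hi,
            "n_tested": int(len(genes)),
            "n_excluded": excluded,
            "timepoints": (tp_a, tp_b),
        }
    )
    return res
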