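"""Welch t, BH adjustment, percentile thresholds, enrichment, differential calls."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from trapquant import (
    benjamini_hochberg,
    crosslink_enrichment,
    differential_association,
    percentile_thresholds,
    welch_t_test,
)
from trapquant.errors import InsufficientDataError
from trapquant.synthetic import simulate_protein_ratio_table


def test_welch_reference_values():
    t, df, p = welch_t_test([1, 2, 3], [4, 5, 6])
    assert t == pytest.approx(-3.674, abs=1e-3)
    assert df == pytest.approx(4.0)
    assert p == pytest.approx(0.02131, abs=2e-4)


def test_welch_degenerate_cases():
    t, df, p = welch_t_test([1, 2, 3], [1, 2, 3])
    assert t == 0.0 and p == 1.0
    assert np.isnan(welch_t_test([5.0], [1, 2, 3])[2])  # insufficient n
    _, _, p_eq = welch_t_test([2.0, 2.0], [2.0, 2.0])
    assert p_eq == 1.0
    _, _, p_ne = welch_t_test([2.0, 2.0], [3.0, 3.0])
    assert 0.0 < p_ne < 1e-300  # smallest representable, not zero


# ----------------------------------------------------------------------
def test_bh_hand_computed_examples():
    np.testing.assert_allclose(
        benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
    )
    np.testing.assert_allclose(benjamini_hochberg([0.03]), [0.03])
    q = benjamini_hochberg([0.5, np.nan, 0.01])
    assert np.isnan(q[1])
    np.testing.assert_allclose(q[[0, 2]], [0.5, 0.02])  # m = 2


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        benjamini_hochberg([0.1, 1.2])


def _naive_bh(p):
    """O(m^2) min-over-suffix definition."""
    p = np.asarray(p, float)
    q = np.full_like(p, np.nan)
    obs = np.flatnonzero(~np.isnan(p))
    m = len(obs)
    order = obs[np.argsort(p[obs], kind="mergesort")]
    for i, gi in enumerate(order):
        q[gi] = min(min(p[order[j]] * m / (j + 1) for j in range(i, m)), 1.0)
    return q


def test_bh_matches_naive_and_statsmodels(rng):
    for _ in range(300):
        n = int(rng.integers(1, 25))
        p = rng.uniform(0, 1, n)
        p[rng.random(n) < 0.2] = np.nan
        q = benjamini_hochberg(p)
        np.testing.assert_allclose(q, _naive_bh(p), rtol=1e-12, equal_nan=True)
        obs = ~np.isnan(p)
        if obs.sum():
            sm = multipletests(p[obs], method="fdr_bh")[1]
            np.testing.assert_allclose(q[obs], sm, rtol=1e-10)


def test_bh_monotone_and_dominates_p(rng):
    p = np.sort(rng.uniform(0, 1, 50))
    q = benjamini_hochberg(p)
    assert (np.diff(q) >= -1e-15).all()
    assert (q >= p - 1e-15).all()


# ----------------------------------------------------------------------
def test_percentile_type7_examples():
    assert percentile_thresholds(np.arange(11.0)) == (1.0, 9.0)
    assert percentile_thresholds([3.0] * 12) == (3.0, 3.0)
    sym = np.concatenate([np.linspace(-2, 2, 41)])
    p10, p90 = percentile_thresholds(sym)
    assert p10 == pytest.approx(-p90)


def test_percentile_matches_brute_force_interpolation(rng):
    for _ in range(200):
        x = rng.normal(0, 1, int(rng.integers(10, 60)))
        p10, p90 = percentile_thresholds(x)
        s = np.sort(x)
        for qq, got in ((0.1, p10), (0.9, p90)):
            h = (len(s) - 1) * qq
            lo, hi = int(np.floor(h)), int(np.ceil(h))
            exp = s[lo] + (h - lo) * (s[hi] - s[lo])
            assert got == pytest.approx(exp, rel=1e-12)


def test_percentile_insufficient_data():
    with pytest.raises(InsufficientDataError):
        percentile_thresholds([0.0] * 9)


# ----------------------------------------------------------------------
def _enrichment_frames():
    genes = ["exclusive", "enriched", "smallfc", "weak", "flat"]
    rng = np.random.default_rng(0)
    base = {
        "exclusive": (12.0, np.nan),
        "enriched": (13.0, 12.0),   # FC = 2
        "smallfc": (12.25, 12.0),   # FC ~ 1.19
        "weak": (13.6, 12.0),       # big FC but noisy
        "flat": (12.0, 12.0),
    }
    cl, noncl = {}, {}
    for g, (mc, mn) in base.items():
        noise = 0.05 if g != "weak" else 1.4
        cl[g] = mc + rng.normal(0, noise, 4) if not np.isnan(mc) else [np.nan] * 4
        noncl[g] = mn + rng.normal(0, noise, 4) if not np.isnan(mn) else [np.nan] * 4
    idx = pd.Index(genes, name="gene")
    return (
        pd.DataFrame(cl).T.set_axis(idx),
        pd.DataFrame(noncl).T.set_axis(idx),
    )


def test_crosslink_enrichment_rules():
    cl, noncl = _enrichment_frames()
    res = crosslink_enrichment(cl, noncl)
    assert bool(res.loc["exclusive", "enriched"]) and bool(
        res.loc["exclusive", "exclusive_to_cl"]
    )
    assert bool(res.loc["enriched", "enriched"])
    # significant but FC below 1.5: not enriched
    assert res.loc["smallfc", "q_value"] < 0.05
    assert not bool(res.loc["smallfc", "enriched"])
    # large FC but non-significant: not enriched
    assert res.loc["weak", "fc"] > 1.5
    assert not bool(res.loc["weak", "enriched"])


def test_crosslink_enrichment_omits_absent_genes():
    cl, noncl = _enrichment_frames()
    cl.loc["ghost"] = np.nan
    noncl.loc["ghost"] = np.nan
    res = crosslink_enrichment(cl, noncl)
    assert "ghost" not in res.index


# ----------------------------------------------------------------------
def test_differential_excludes_insufficient_quantitation():
    pq, _ = simulate_protein_ratio_table(50, 3, 0.1, seed=4)
    # knock one gene down to a single quantitation at t10min
    gene = pq.ratios.index[0]
    pq.ratios.loc[gene, ("t10min", 1)] = np.nan
    pq.ratios.loc[gene, ("t10min", 2)] = np.nan
    res = differential_association(pq)
    assert gene not in res.index
    assert res.attrs["n_excluded"] == 1


def test_differential_percentile_gate_fraction():
    """By construction ~20% of tested genes lie beyond the 10th/90th percentiles."""
    pq, _ = simulate_protein_ratio_table(1000, 3, 0.2, seed=8)
    res = differential_association(pq)
    beyond = ((res["log2fc"] > res.attrs["p90"]) | (res["log2fc"] < res.attrs["p10"])).mean()
    assert beyond == pytest.approx(0.2, abs=0.01)
    # flags respect the published invariant
    expect = (res["p_value"] < 0.05) & (
        (res["log2fc"] > res.attrs["p90"]) | (res["log2fc"] < res.attrs["p10"])
    )
    assert (res["significant_primary"] == expect).all()


def test_differential_gene_order_invariance():
    pq, _ = simulate_protein_ratio_table(60, 3, 0.2, fraction_changed=0.2, seed=12)
    res1 = differential_association(pq)
    shuffled = type(pq)(
        pq.ratios.sample(frac=1.0, random_state=1),
        pq.n_peptides.sample(frac=1.0, random_state=1),
        pq.heavy_detected.sample(frac=1.0, random_state=1),
    )
    res2 = differential_association(shuffled)
    pd.testing.assert_frame_equal(res1, res2)


def test_differential_joins_enrichment():
    pq, _ = simulate_protein_ratio_table(30, 3, 0.2, fraction_changed=0.3, seed=3)
    enr = pd.DataFrame(
        {"enriched": [True] * 15 + [False] * 15}, index=pq.ratios.index
    )
    res = differential_association(pq, enrichment=enr)
    assert (res["significant_rbp"] == (res["significant_primary"] & res["crosslink_enriched"])).all()
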