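"""Ratio computation, singleton masking, aggregation, detection filters."""

import itertools

import numpy as np
import pandas as pd
import pytest

from trapquant import (
    SampleDesign,
    aggregate_protein_ratios,
    apply_detection_filters,
    compute_peptide_ratios,
    mask_single_peptide_quantitations,
)
from trapquant.errors import DesignError
from trapquant.quantify import peptide_key

from conftest import make_fim


def _design():
    rows = []
    for tp in ("t10min", "t1h"):
        for rep in (1, 2, 3):
            rows.append(
                {"run_id": f"{tp}_r{rep}", "acquisition": "DIA", "timepoint": tp,
                 "replicate": rep, "light_condition": "arsenite",
                 "heavy_condition": "mock", "crosslinked": True}
            )
    return SampleDesign(pd.DataFrame(rows))


def _one_run_design():
    return SampleDesign(
        pd.DataFrame(
            [{"run_id": "t10min_r1", "acquisition": "DIA", "timepoint": "t10min",
              "replicate": 1, "light_condition": "a", "heavy_condition": "m",
              "crosslinked": True}]
        )
    )


def test_compute_ratios_linear_log2_and_missing():
    design = _one_run_design()
    vals = pd.DataFrame(
        {"t10min_r1H": [5.0, np.nan, 3.0], "t10min_r1L": [10.0, 4.0, 4.0]},
        index=["f1", "f2", "f3"],
    )
    lin = compute_peptide_ratios(make_fim(vals, "linear"), design)
    assert lin.set_index("feature_id").loc["f1", "ratio_LH"] == pytest.approx(2.0)
    assert np.isnan(lin.set_index("feature_id").loc["f2", "ratio_LH"])  # heavy missing
    log = compute_peptide_ratios(make_fim(vals, "log2"), design)
    # log2 inputs (4.0, 3.0) -> linear ratio 2.0
    assert log.set_index("feature_id").loc["f3", "ratio_LH"] == pytest.approx(2.0)


def test_compute_ratios_unpaired_sample_errors():
    design = _one_run_design()
    vals = pd.DataFrame({"t10min_r1H": [5.0]}, index=["f1"])
    with pytest.raises(DesignError):
        compute_peptide_ratios(make_fim(vals, "linear"), design)


# ----------------------------------------------------------------------
def _ratio_table(groups):
    """groups: dict (gene, tp, rep) -> list of ratios (nan allowed)."""
    rows = []
    for (gene, tp, rep), ratios in groups.items():
        for i, r in enumerate(ratios):
            rows.append(
                {"gene": gene, "feature_id": f"{gene}_p{i}2", "peptide_key": f"{gene}_p{i}",
                 "timepoint": tp, "replicate": rep, "ratio_LH": r, "heavy_quant": not np.isnan(r)}
            )
    return pd.DataFrame(rows)


@pytest.mark.parametrize(
    "ratios,expected",
    [
        ([np.nan, np.nan, 1.3], [np.nan, np.nan, np.nan]),  # lone value masked
        ([1.1, 0.9, np.nan], [1.1, 0.9, np.nan]),           # >= 2 retained
        ([np.nan, np.nan], [np.nan, np.nan]),               # nothing to mask
    ],
)
def test_singleton_masking_rule(ratios, expected):
    table = _ratio_table({("g", "t10min", 1): ratios})
    out = mask_single_peptide_quantitations(table)
    np.testing.assert_array_equal(out["ratio_LH"].to_numpy(), np.array(expected))


def _brute_force_mask(table):
    out = table.copy()
    for _, idx in out.groupby(["gene", "timepoint", "replicate"]).groups.items():
        vals = out.loc[idx, "ratio_LH"]
        if vals.notna().sum() == 1:
            out.loc[idx, "ratio_LH"] = np.nan
    return out


def test_masking_matches_brute_force_on_random_tables(rng):
    for _ in range(200):
        groups = {}
        for g in range(rng.integers(1, 5)):
            for tp in ("t10min", "t1h"):
                for rep in (1, 2):
                    n = int(rng.integers(1, 5))
                    vals = [float(rng.uniform(0.5, 2)) if rng.random() < 0.5 else np.nan
                            for _ in range(n)]
                    groups[(f"g{g}", tp, rep)] = vals
        table = _ratio_table(groups)
        fast = mask_single_peptide_quantitations(table)
        slow = _brute_force_mask(table)
        pd.testing.assert_frame_equal(fast, slow)


# ----------------------------------------------------------------------
def test_aggregation_median_rules():
    table = _ratio_table(
        {
            ("g1", "t10min", 1): [1.0, 2.0, 4.0],
            ("g2", "t10min", 1): [1.0, 2.0, 4.0, 8.0],
        }
    )
    pq = aggregate_protein_ratios(table)
    assert pq.ratios.loc["g1", ("t10min", 1)] == pytest.approx(2.0)
    assert pq.ratios.loc["g2", ("t10min", 1)] == pytest.approx(3.0)  # even-count median


def test_aggregation_median_matches_sorting_oracle(rng):
    """Median equals the sort-based definition for all n <= 6 permutations."""
    for n in range(2, 7):
        base = sorted(rng.uniform(0.1, 10.0, n))
        expected = (base[(n - 1) // 2] + base[n // 2]) / 2.0
        for perm in itertools.islice(itertools.permutations(base), 24):
            pq = aggregate_protein_ratios(_ratio_table({("g", "t10min", 1): list(perm)}))
            assert pq.ratios.loc["g", ("t10min", 1)] == pytest.approx(expected)


def test_aggregation_singleton_after_masking_is_missing():
    table = mask_single_peptide_quantitations(
        _ratio_table({("g", "t10min", 1): [np.nan, np.nan, 1.3]})
    )
    pq = aggregate_protein_ratios(table)
    assert np.isnan(pq.ratios.loc["g", ("t10min", 1)])
    assert pq.n_peptides.loc["g", ("t10min", 1)] == 0


def test_aggregation_requires_two_distinct_peptides():
    # two charge states of one peptide count once: quantity suppressed
    rows = pd.DataFrame(
        [
            {"gene": "g", "feature_id": "P|g|SEQK2", "timepoint": "t10min",
             "replicate": 1, "ratio_LH": 1.2, "heavy_quant": True},
            {"gene": "g", "feature_id": "P|g|SEQK3", "timepoint": "t10min",
             "replicate": 1, "ratio_LH": 1.4, "heavy_quant": True},
        ]
    )
    rows["peptide_key"] = rows["feature_id"].map(peptide_key)
    assert rows["peptide_key"].nunique() == 1
    pq = aggregate_protein_ratios(rows)
    assert np.isnan(pq.ratios.loc["g", ("t10min", 1)])


# ----------------------------------------------------------------------
def _pq_for_filters(heavy_t10, heavy_t1h, ratios_t10=3, max_pep=2):
    groups = {}
    for rep in (1, 2, 3):
        n = max_pep if rep <= ratios_t10 else 0
        vals_10 = [1.0] * n if rep <= heavy_t10 else [np.nan] * max(n, 1)
        groups[("g", "t10min", rep)] = vals_10 if rep <= heavy_t10 else [np.nan]
        groups[("g", "t1h", rep)] = [1.0] * max_pep if rep <= heavy_t1h else [np.nan]
    return aggregate_protein_ratios(_ratio_table(groups))


def test_processed_filter_both_timepoints():
    design = _design()
    ok = apply_detection_filters(_pq_for_filters(3, 2), design)
    assert bool(ok.processed.loc["g"])
    bad = apply_detection_filters(_pq_for_filters(2, 1), design)
    assert not bool(bad.processed.loc["g"])  # fails "both time points"
    assert bool(bad.stage1_pass.loc["g"])    # still passes any-time-point stage


def test_processed_filter_min_peptides():
    design = _design()
    pq = apply_detection_filters(_pq_for_filters(3, 3, max_pep=1), design)
    assert not bool(pq.processed.loc["g"])  # max one peptide anywhere


def test_filters_are_monotone(small_sim):
    """Tightening min_reps or min_peptides never adds genes."""
    from trapquant import build_intensity_matrix
    mat = build_intensity_matrix(small_sim.dia_records, small_sim.dia_design)
    table = mask_single_peptide_quantitations(
        compute_peptide_ratios(mat, small_sim.dia_design)
    )
    pq = aggregate_protein_ratios(table)
    base = apply_detection_filters(pq, small_sim.dia_design, min_peptides=2, min_reps=2)
    tight_rep = apply_detection_filters(pq, small_sim.dia_design, min_peptides=2, min_reps=3)
    tight_pep = apply_detection_filters(pq, small_sim.dia_design, min_peptides=3, min_reps=2)
    assert set(tight_rep.processed[tight_rep.processed].index) <= set(
        base.processed[base.processed].index
    )
    assert set(tight_pep.processed[tight_pep.processed].index) <= set(
        base.processed[base.processed].index
    )


def test_aggregation_permutation_invariant(rng):
    table = _ratio_table(
        {("g", "t10min", 1): list(rng.uniform(0.5, 2.0, 5)),
         ("g", "t1h", 2): list(rng.uniform(0.5, 2.0, 4))}
    )
    shuffled = table.sample(frac=1.0, random_state=9).reset_index(drop=True)
    a = aggregate_protein_ratios(table)
    b = aggregate_protein_ratios(shuffled)
    pd.testing.assert_frame_equal(a.ratios, b.ratios)
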