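"""Ingestion: SILAC tag parsing, dialect readers, matrix pivot."""

import numpy as np
import pandas as pd
import pytest

from trapquant import (
    SampleDesign,
    build_intensity_matrix,
    parse_silac_precursor_id,
    read_diann_report,
    read_maxquant_peptides,
    read_maxquant_protein_groups,
)
from trapquant.errors import (
    DuplicateCellError,
    MalformedChannelError,
    SchemaError,
    UnknownRunError,
    UnlabeledPrecursorError,
)


@pytest.mark.parametrize(
    "raw,channel,stripped",
    [
        ("SEQVENCEK(SILAC-K-H)2", "heavy", "SEQVENCEK2"),
        ("SEQVENCER(SILAC-R-L)3", "light", "SEQVENCER3"),
        ("AK(SILAC-K-H)SEQR(SILAC-R-H)2", "heavy", "AKSEQR2"),
    ],
)
def test_parse_silac_tags(raw, channel, stripped):
    assert parse_silac_precursor_id(raw) == (channel, stripped)


def test_parse_silac_errors_and_idempotence():
    with pytest.raises(MalformedChannelError):
        parse_silac_precursor_id("PEPK(SILAC-K-H)TIDER(SILAC-R-L)2")
    with pytest.raises(UnlabeledPrecursorError):
        parse_silac_precursor_id("PEPTIDEK2")
    with pytest.raises(UnlabeledPrecursorError):
        parse_silac_precursor_id("PEPK(silac-k-h)2")  # tags are case-exact
    # a stripped id has no tags left: re-parsing raises unlabeled
    _, stripped = parse_silac_precursor_id("SEQVENCEK(SILAC-K-H)2")
    assert "(SILAC-" not in stripped


def _diann_fixture(path, rows):
    cols = ["Run", "Protein.Ids", "Genes", "Precursor.Id",
            "Precursor.Translated", "Q.Value", "Translated.Q.Value"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
    return path


def test_read_diann_report_filters_and_missing(tmp_path):
    path = _diann_fixture(
        tmp_path / "report.tsv",
        [
            ["r1", "P1", "GA", "AAAK(SILAC-K-H)2", 100.0, 0.001, 0.001],
            ["r1", "P1", "GA", "AAAK(SILAC-K-L)2", 50.0, 0.001, 0.02],  # fails tQ
            ["r1", "P2", "GB", "CCCR(SILAC-R-L)2", 80.0, 0.02, 0.001],  # fails Q
            ["r1", "P2", "GB", "CCCR(SILAC-R-H)2", "", 0.001, 0.001],   # empty intensity
        ],
    )
    rec = read_diann_report(path)
    assert len(rec) == 2
    assert rec["channel"].tolist() == ["heavy", "heavy"]
    empty = rec[rec["precursor_id"] == "CCCR2"]
    assert empty["intensity"].isna().all()  # kept, missing intensity
    # feature identity concatenates protein ids, gene, stripped precursor
    assert rec["feature_id"].iloc[0] == "P1|GA|AAAK2"


def test_read_diann_missing_column_names_it(tmp_path):
    df = pd.DataFrame({"Run": ["r1"], "Genes": ["G"]})
    df.to_csv(tmp_path / "bad.tsv", sep="\t", index=False)
    with pytest.raises(SchemaError, match="Protein.Ids"):
        read_diann_report(tmp_path / "bad.tsv")


def test_read_diann_tolerant_column_matching(tmp_path):
    # dot/space interchangeable, case-insensitive
    rows = [["r1", "P1", "GA", "AAAK(SILAC-K-H)2", 100.0, 0.001, 0.001]]
    df = pd.DataFrame(rows, columns=["run", "protein ids", "GENES", "Precursor Id",
                                     "precursor.translated", "q value", "translated q value"])
    df.to_csv(tmp_path / "drift.tsv", sep="\t", index=False)
    rec = read_diann_report(tmp_path / "drift.tsv")
    assert len(rec) == 1 and rec["intensity"].iloc[0] == 100.0


def test_read_maxquant_peptides(tmp_path):
    df = pd.DataFrame(
        {
            "Sequence": ["AAAK", "CCCK", "DDDR", "EEEK"],
            "Gene names": ["GA", "GB", "GC", "GD"],
            "Proteins": ["P1", "P2", "P3", "P4"],
            "Unique (Groups)": ["yes", "yes", "yes", "no"],
            "Intensity L t10_r1": [10.0, 0.0, 5.0, 7.0],
            "Intensity H t10_r1": [20.0, 4.0, 6.0, 8.0],
        }
    )
    df.to_csv(tmp_path / "peptides.txt", sep="\t", index=False)
    rec = read_maxquant_peptides(tmp_path / "peptides.txt")
    assert set(rec["peptide_id"]) == {"AAAK", "CCCK", "DDDR"}  # shared peptide dropped
    ccc_l = rec[(rec["peptide_id"] == "CCCK") & (rec["channel"] == "light")]
    assert ccc_l["intensity"].isna().all()  # zero -> missing
    assert len(rec) == 6


def test_read_maxquant_peptides_requires_intensities(tmp_path):
    pd.DataFrame({"Sequence": ["A"], "Gene names": ["G"], "Proteins": ["P"]}).to_csv(
        tmp_path / "p.txt", sep="\t", index=False
    )
    with pytest.raises(SchemaError):
        read_maxquant_peptides(tmp_path / "p.txt")


def test_read_protein_groups_flags_and_inversion(tmp_path):
    df = pd.DataFrame(
        {
            "Gene names": ["GA", "GB", "KRT18", "GD", "GE"],
            "Majority protein IDs": ["P1", "REV__P2", "P3", "CON__P4", "P5"],
            "Ratio H/L normalized t10_r1": [0.5, 1.0, 1.0, 1.0, 2.0],
            "Reverse": ["", "+", "", "", ""],
            "Potential contaminant": ["", "", "", "+", ""],
        }
    )
    df.to_csv(tmp_path / "pg.txt", sep="\t", index=False)
    pg = read_maxquant_protein_groups(tmp_path / "pg.txt")
    assert set(pg["gene"]) == {"GA", "GE"}
    assert pg.set_index("gene").loc["GA", "ratio_LH t10_r1"] == pytest.approx(2.0)
    assert pg.set_index("gene").loc["GE", "ratio_LH t10_r1"] == pytest.approx(0.5)


# ----------------------------------------------------------------------
def _design(runs):
    return SampleDesign(
        pd.DataFrame(
            [
                {"run_id": r, "acquisition": "DIA", "timepoint": "t10min",
                 "replicate": i + 1, "light_condition": "arsenite",
                 "heavy_condition": "mock", "crosslinked": True}
                for i, r in enumerate(runs)
            ]
        )
    )


def _records(rows):
    return pd.DataFrame(
        rows, columns=["run_id", "feature_id", "gene", "protein_ids", "channel", "intensity"]
    )


def test_build_matrix_basic_and_channel_split():
    rec = _records(
        [
            ["r1", "f1", "GA", "P1", "heavy", 1.0],
            ["r1", "f1", "GA", "P1", "light", 2.0],
            ["r1", "f2", "GB", "P2", "heavy", 3.0],
            ["r2", "f2", "GB", "P2", "heavy", 4.0],
        ]
    )
    fim = build_intensity_matrix(rec, _design(["r1", "r2"]))
    # H and L of the same run are distinct sample units
    assert set(fim.samples) == {"r1H", "r1L", "r2H", "r2L"}
    assert fim.values.loc["f1", "r1H"] == 1.0
    assert fim.values.loc["f1", "r1L"] == 2.0
    # pivot conserves values: non-missing cells == record count
    assert fim.values.notna().sum().sum() == 4


def test_build_matrix_unknown_run_and_duplicates():
    with pytest.raises(UnknownRunError):
        build_intensity_matrix(
            _records([["ghost", "f1", "GA", "P1", "heavy", 1.0]]), _design(["r1"])
        )
    dup = _records(
        [
            ["r1", "f1", "GA", "P1", "heavy", 1.0],
            ["r1", "f1", "GA", "P1", "heavy", 2.0],
        ]
    )
    with pytest.raises(DuplicateCellError):
        build_intensity_matrix(dup, _design(["r1"]))


def test_build_matrix_drops_multi_gene_features():
    rec = _records(
        [
            ["r1", "f1", "GA;GB", "P1;P2", "heavy", 1.0],
            ["r1", "f2", "GC", "P3", "heavy", 2.0],
        ]
    )
    fim = build_intensity_matrix(rec, _design(["r1"]))
    assert list(fim.values.index) == ["f2"]


def test_pivot_conserves_values_random(rng):
    """Property: every non-missing input intensity lands in exactly one cell."""
    runs = ["r1", "r2", "r3"]
    rows = []
    for f in range(20):
        for r in runs:
            for ch in ("heavy", "light"):
                if rng.random() < 0.7:
                    rows.append([r, f"f{f}", f"G{f}", f"P{f}", ch, float(rng.uniform(1, 100))])
    rec = _records(rows)
    fim = build_intensity_matrix(rec, _design(runs))
    assert int(fim.values.notna().sum().sum()) == len(rec)
    total_in = rec["intensity"].sum()
    assert np.isclose(np.nansum(fim.values.to_numpy()), total_in)
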