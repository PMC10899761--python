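"""Readers for DIA-NN- and MaxQuant-dialect quantitation tables.

Both search engines emit tab-separated text. The DIA-NN report is long
format (one row per precursor per run) with SILAC channels encoded as
``(SILAC-K-H/L)`` / ``(SILAC-R-H/L)`` tags inside ``Precursor.Id``; the
MaxQuant tables are wide, with per-experiment heavy/light intensity
columns. Everything converges on a common record layout and, via
:func:`build_intensity_matrix`, a feature x sample-unit matrix.

Conventions applied throughout (see docs/methods.md):

* zero or blank intensity is missing — an MS intensity of zero means
  non-detection, never a measured zero;
* features whose Genes field carries multiple ";"-separated symbols are
  dropped (counted and logged) before any per-gene aggregation;
* column-name matching is exact first, then tolerant (case-insensitive,
  "." and " " interchangeable) to absorb dialect drift between tool
  versions.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .design import CHANNEL_SUFFIX, SampleDesign
from .errors import (
    DuplicateCellError,
    MalformedChannelError,
    SchemaError,
    UnknownRunError,
    UnlabeledPrecursorError,
)
from .matrix import FeatureIntensityMatrix

logger = logging.getLogger(__name__)

HEAVY_TAGS = ("(SILAC-K-H)", "(SILAC-R-H)")
LIGHT_TAGS = ("(SILAC-K-L)", "(SILAC-R-L)")
_ALL_TAGS = HEAVY_TAGS + LIGHT_TAGS


# ----------------------------------------------------------------------
# SILAC channel parsing
# ----------------------------------------------------------------------
def parse_silac_precursor_id(raw_id: str) -> tuple[str, str]:
    """Split a tagged precursor id into (channel, stripped id).

    A precursor is heavy iff its id contains ``(SILAC-K-H)`` and/or
    ``(SILAC-R-H)``, light for the L variants; the stripped id has all
    four tags removed so the heavy and light forms of one precursor
    collapse to the same identifier. Tag matching is case-exact.

    Raises
    ------
    MalformedChannelError
        if both heavy and light tags occur in one id.
    UnlabeledPrecursorError
        if no tag occurs.
    """
    if not raw_id:
        raise UnlabeledPrecursorError("empty precursor id")
    has_heavy = any(t in raw_id for t in HEAVY_TAGS)
    has_light = any(t in raw_id for t in LIGHT_TAGS)
    if has_heavy and has_light:
        raise MalformedChannelError(f"both H and L tags in {raw_id!r}")
    if not (has_heavy or has_light):
        raise UnlabeledPrecursorError(f"no SILAC channel tag in {raw_id!r}")
    stripped = raw_id
    for tag in _ALL_TAGS:
        stripped = stripped.replace(tag, "")
    return ("heavy" if has_heavy else "light"), stripped


# ----------------------------------------------------------------------
# column resolution
# ----------------------------------------------------------------------
def _canon(name: str) -> str:
    return re.sub(r"[.\s]+", " ", name).strip().lower()


def _resolve_columns(df: pd.DataFrame, wanted: list[str], path) -> dict[str, str]:
    """Map wanted column names onto actual ones (exact, then tolerant)."""
    out: dict[str, str] = {}
    canon_map: dict[str, str] = {}
    for c in df.columns:
        canon_map.setdefault(_canon(c), c)
    for w in wanted:
        if w in df.columns:
            out[w] = w
        elif _canon(w) in canon_map:
            out[w] = canon_map[_canon(w)]
        else:
            raise SchemaError(f"{path}: missing mandatory column {w!r}")
    return out


def _to_intensity(series: pd.Series, path, label: str) -> pd.Series:
    """Numeric coercion with zero->missing; counts unparseable cells."""
    vals = pd.to_numeric(series, errors="coerce")
    bad = series.notna() & (series.astype(str).str.strip() != "") & vals.isna()
    if bad.any():
        logger.warning("%s: %d unreadable %s cells set to missing", path, int(bad.sum()), label)
    vals = vals.where(vals > 0)  # zero-as-missing convention
    if (vals.dropna() < 0).any():
        raise SchemaError(f"{path}: negative intensity in {label}")
    return vals


# ----------------------------------------------------------------------
# DIA-NN report
# ----------------------------------------------------------------------
def read_diann_report(
    path: str | Path,
    q_max: float = 0.01,
    translated_q_max: float = 0.01,
    on_unlabeled: str = "error",
) -> pd.DataFrame:
    """Read a DIA-NN ``Report.tsv``-dialect file into precursor records.

    Rows failing either the precursor Q-value or the translated Q-value
    filter (both 1% by default) are removed. Feature identity is the
    concatenation of Protein.Ids, Genes and the channel-stripped
    Precursor.Id, so both SILAC channels of one precursor share one
    feature id.

    Parameters
    ----------
    on_unlabeled
        'error' (default) raises on ids without a SILAC tag; 'drop'
        removes them with a logged count.

    Returns
    -------
    DataFrame with columns run_id, protein_ids, gene, precursor_id,
    feature_id, channel, intensity, q_value, translated_q.
    """
    if not (0 < q_max <= 1) or not (0 < translated_q_max <= 1):
        raise ValueError("q thresholds must lie in (0, 1]")
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = _resolve_columns(
        df,
        ["Run", "Protein.Ids", "Genes", "Precursor.Id",
         "Precursor.Translated", "Q.Value", "Translated.Q.Value"],
        path,
    )
    q = pd.to_numeric(df[cols["Q.Value"]], errors="coerce")
    tq = pd.to_numeric(df[cols["Translated.Q.Value"]], errors="coerce")
    keep = (q <= q_max) & (tq <= translated_q_max)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("%s: %d rows removed by Q-value filters", path, n_drop)
    df = df.loc[keep].reset_index(drop=True)
    q, tq = q[keep].reset_index(drop=True), tq[keep].reset_index(drop=True)

    channels, stripped = [], []
    unlabeled = []
    for i, raw in enumerate(df[cols["Precursor.Id"]]):
        try:
            ch, sid = parse_silac_precursor_id(str(raw))
        except UnlabeledPrecursorError:
            if on_unlabeled == "drop":
                unlabeled.append(i)
                ch, sid = "", ""
            else:
                raise
        channels.append(ch)
        stripped.append(sid)

    rec = pd.DataFrame(
        {
            "run_id": df[cols["Run"]],
            "protein_ids": df[cols["Protein.Ids"]],
            "gene": df[cols["Genes"]],
            "precursor_id": stripped,
            "channel": channels,
            "intensity": _to_intensity(df[cols["Precursor.Translated"]], path, "intensity"),
            "q_value": q,
            "translated_q": tq,
        }
    )
    if unlabeled:
        logger.warning("%s: %d unlabeled precursors dropped", path, len(unlabeled))
        rec = rec.drop(index=unlabeled).reset_index(drop=True)
    rec["feature_id"] = (
        rec["protein_ids"].astype(str)
        + "|" + rec["gene"].astype(str)
        + "|" + rec["precursor_id"].astype(str)
    )
    return rec


# ----------------------------------------------------------------------
# MaxQuant tables
# ----------------------------------------------------------------------
def read_maxquant_peptides(path: str | Path) -> pd.DataFrame:
    """Read a MaxQuant ``peptides.txt``-dialect file (unique peptides only).

    Returns a long frame with one row per (peptide, experiment, channel):
    columns peptide_id, gene, protein_ids, experiment, channel, intensity.
    Peptides not flagged unique are dropped; zero intensities are missing.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = _resolve_columns(df, ["Sequence", "Gene names", "Proteins"], path)
    unique_col = None
    for cand in ("Unique (Groups)", "Unique (Proteins)", "Unique"):
        try:
            unique_col = _resolve_columns(df, [cand], path)[cand]
            break
        except SchemaError:
            continue
    if unique_col is not None:
        n0 = len(df)
        df = df[df[unique_col].astype(str).str.strip().str.lower() == "yes"]
        logger.info("%s: %d non-unique peptides dropped", path, n0 - len(df))
    df = df.reset_index(drop=True)

    pat = re.compile(r"^Intensity ([HL]) (.+)$")
    int_cols = [(c, *pat.match(c).groups()) for c in df.columns if pat.match(c)]
    if not int_cols:
        raise SchemaError(f"{path}: no 'Intensity H/L <experiment>' columns found")

    frames = []
    for col, hl, exp in int_cols:
        frames.append(
            pd.DataFrame(
                {
                    "peptide_id": df[cols["Sequence"]],
                    "gene": df[cols["Gene names"]],
                    "protein_ids": df[cols["Proteins"]],
                    "experiment": exp,
                    "channel": "heavy" if hl == "H" else "light",
                    "intensity": _to_intensity(df[col], path, col),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


_KERATIN = re.compile(r"(?:^|;)\s*KRT", re.IGNORECASE)


def read_maxquant_protein_groups(path: str | Path) -> pd.DataFrame:
    """Read a ``proteinGroups.txt``-dialect file.

    Contaminant, reverse-decoy and keratin rows are removed; MaxQuant's
    normalized heavy/light ratios are inverted to light/heavy (treated
    over control). Returns one row per protein group with ``gene``,
    ``protein_ids``, per-experiment ``ratio_LH <exp>`` columns and any
    per-sample ``Intensity <sample>`` columns found.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = _resolve_columns(df, ["Gene names", "Majority protein IDs"], path)

    n0 = len(df)
    for flag in ("Reverse", "Potential contaminant", "Contaminant"):
        if flag in df.columns:
            df = df[df[flag].fillna("").str.strip() != "+"]
    df = df[~df[cols["Gene names"]].fillna("").str.contains(_KERATIN)]
    logger.info("%s: %d contaminant/reverse/keratin rows removed", path, n0 - len(df))
    df = df.reset_index(drop=True)

    out = pd.DataFrame(
        {"gene": df[cols["Gene names"]], "protein_ids": df[cols["Majority protein IDs"]]}
    )
    ratio_pat = re.compile(r"^Ratio H/L normalized (.+)$")
    found_ratio = False
    for c in df.columns:
        m = ratio_pat.match(c)
        if m:
            found_ratio = True
            hl = pd.to_numeric(df[c], errors="coerce")
            out[f"ratio_LH {m.group(1)}"] = (1.0 / hl).where(hl > 0)
        elif c.startswith("Intensity ") and not c.startswith("Intensity L") \
                and not c.startswith("Intensity H"):
            out[c] = _to_intensity(df[c], path, c)
        elif re.match(r"^Intensity [HL] ", c):
            out[c.replace("Intensity", "intensity", 1)] = _to_intensity(df[c], path, c)
    if not found_ratio and not any(c.startswith(("Intensity", "intensity")) for c in out.columns):
        raise SchemaError(f"{path}: no ratio or intensity columns found")
    return out


# ----------------------------------------------------------------------
# pivot to matrix
# ----------------------------------------------------------------------
def drop_multi_gene_features(records: pd.DataFrame) -> pd.DataFrame:
    """Drop records whose gene field names several ";"-separated symbols."""
    multi = records["gene"].astype(str).str.contains(";")
    if multi.any():
        logger.info("dropping %d gene-ambiguous records", int(multi.sum()))
    return records.loc[~multi].reset_index(drop=True)


def build_intensity_matrix(
    records: pd.DataFrame,
    design: SampleDesign,
    drop_multi_gene: bool = True,
) -> FeatureIntensityMatrix:
    """Pivot long precursor/peptide records to a feature x sample matrix.

    Sample units are ``<run_id>H`` / ``<run_id>L``. Every record's
    run_id must be present in the design; design samples with no records
    become all-missing columns (warned). Duplicate (feature, sample)
    pairs raise: the pivot presumes uniqueness, silent aggregation would
    hide upstream identity clashes.
    """
    rec = records.copy()
    if "feature_id" not in rec.columns:
        rec["feature_id"] = rec["peptide_id"].astype(str)
    if drop_multi_gene:
        rec = drop_multi_gene_features(rec)

    known = set(design.run_ids)
    unknown = set(rec["run_id"]) - known
    if unknown:
        raise UnknownRunError(f"records reference run(s) absent from design: {sorted(unknown)}")

    rec["sample"] = rec["run_id"].astype(str) + rec["channel"].map(CHANNEL_SUFFIX)
    dup = rec.duplicated(subset=["feature_id", "sample"], keep=False)
    if dup.any():
        pairs = rec.loc[dup, ["feature_id", "sample"]].drop_duplicates()
        raise DuplicateCellError(
            f"{len(pairs)} duplicate (feature, sample) cell(s), e.g. "
            f"{tuple(pairs.iloc[0])}"
        )

    wide = rec.pivot(index="feature_id", columns="sample", values="intensity")
    expected = list(design.sample_units().index)
    missing_cols = [s for s in expected if s not in wide.columns]
    if missing_cols:
        logger.warning("design sample(s) with no records: %s", missing_cols)
        for s in missing_cols:
            wide[s] = np.nan
    wide = wide[expected].sort_index()

    ann = (
        rec.drop_duplicates("feature_id")
        .set_index("feature_id")[["gene", "protein_ids"]]
        .loc[wide.index]
    )
    return FeatureIntensityMatrix(wide, ann, "linear")


def write_long_format(records: pd.DataFrame, path: str | Path) -> None:
    """Canonical Sample/Feature/Intensity long-format TSV."""
    rec = records.copy()
    rec["sample"] = rec["run_id"].astype(str) + rec["channel"].map(CHANNEL_SUFFIX)
    rec[["sample", "feature_id", "intensity"]].rename(
        columns={"sample": "Sample", "feature_id": "Feature", "intensity": "Intensity"}
    ).to_csv(path, sep="\t", index=False)
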