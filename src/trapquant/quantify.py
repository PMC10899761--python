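"""Peptide ratios, singleton masking, protein aggregation, detection filters.

The quantitation chain mirrors the SILAC processing narrative:

1. light/heavy ratio per peptide per (timepoint, replicate), missing if
   either channel is missing;
2. singleton masking — a gene represented by exactly one non-missing
   peptide ratio in a sample has that lone value set to missing;
3. per-gene median over the surviving peptide ratios, with the protein
   value kept only when backed by >= 2 distinct quantitated peptides;
4. detection filters: stage 1 keeps genes quantified in >= 2 of 3
   replicates at any time point; stage 2 (the "processed dataset")
   additionally requires >= 2 peptides and heavy-control detection in
   >= 2 of 3 replicates at BOTH time points.

"Peptide" here means a distinct channel-stripped sequence ignoring
charge: two charge states of one precursor count once toward the
two-peptide rules.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import CHANNEL_SUFFIX, SampleDesign
from .errors import DesignError
from .matrix import FeatureIntensityMatrix

logger = logging.getLogger(__name__)

_TRAILING_CHARGE = re.compile(r"\d+$")


def peptide_key(feature_id: str) -> str:
    """Collapse a precursor feature id to its peptide (drop trailing charge)."""
    precursor = feature_id.rsplit("|", 1)[-1]
    return _TRAILING_CHARGE.sub("", precursor)


# ----------------------------------------------------------------------
def compute_peptide_ratios(
    matrix: FeatureIntensityMatrix, design: SampleDesign
) -> pd.DataFrame:
    """Light/heavy ratio per feature per (timepoint, replicate).

    Ratios are on linear scale (2**(L - H) for log2/glog input). A ratio
    is missing whenever either channel intensity is missing. Returns a
    long frame with columns gene, feature_id, peptide_key, timepoint,
    replicate, ratio_LH, heavy_quant (heavy channel present).
    """
    vals = matrix.values
    log_scale = matrix.scale in ("log2", "glog")
    frames = []
    for tp, reps in design.timepoint_replicates().items():
        for rep in reps:
            run = design.run_for(tp, rep)
            col_l = f"{run}{CHANNEL_SUFFIX['light']}"
            col_h = f"{run}{CHANNEL_SUFFIX['heavy']}"
            for col in (col_l, col_h):
                if col not in vals.columns:
                    raise DesignError(f"matrix lacks sample unit {col!r}")
            light, heavy = vals[col_l], vals[col_h]
            ratio = (
                np.power(2.0, light - heavy) if log_scale else light / heavy
            )
            ratio = ratio.where(light.notna() & heavy.notna())
            frames.append(
                pd.DataFrame(
                    {
                        "gene": matrix.features["gene"],
                        "feature_id": vals.index,
                        "timepoint": tp,
                        "replicate": rep,
                        "ratio_LH": ratio.to_numpy(),
                        "heavy_quant": heavy.notna().to_numpy(),
                    }
                )
            )
    table = pd.concat(frames, ignore_index=True)
    table["peptide_key"] = table["feature_id"].map(peptide_key)
    return table


def mask_single_peptide_quantitations(table: pd.DataFrame) -> pd.DataFrame:
    """Null out lone peptide ratios per (gene, timepoint, replicate).

    If a group has exactly one non-missing ratio, that value becomes
    missing; groups with zero or >= 2 non-missing values are untouched.
    """
    out = table.copy()
    counts = out.groupby(["gene", "timepoint", "replicate"])["ratio_LH"].transform(
        lambda s: s.notna().sum()
    )
    singleton = (counts == 1) & out["ratio_LH"].notna()
    if singleton.any():
        logger.info("singleton masking removed %d lone quantitations", int(singleton.sum()))
    out.loc[singleton, "ratio_LH"] = np.nan
    return out


# ----------------------------------------------------------------------
@dataclass
class ProteinQuantTable:
    """Per-gene protein quantitation across (timepoint, replicate) samples.

    ``ratios`` holds linear light/heavy medians (NaN = not quantified);
    ``n_peptides`` the count of distinct quantitated peptides behind each
    cell; ``heavy_detected`` whether the heavy control channel had >= 2
    quantitated peptides. ``stage1_pass`` / ``processed`` are filled by
    :func:`apply_detection_filters`; ``filter_log`` records casualty
    counts per stage.
    """

    ratios: pd.DataFrame = field(repr=False)
    n_peptides: pd.DataFrame = field(repr=False)
    heavy_detected: pd.DataFrame = field(repr=False)
    stage1_pass: pd.Series | None = None
    processed: pd.Series | None = None
    filter_log: dict = field(default_factory=dict)

    @property
    def genes(self) -> pd.Index:
        return self.ratios.index

    def timepoints(self) -> list[str]:
        return sorted(self.ratios.columns.get_level_values(0).unique())

    def ratios_at(self, timepoint: str) -> pd.DataFrame:
        return self.ratios[timepoint]

    def processed_view(self) -> "ProteinQuantTable":
        """Restrict all tables to genes with processed_flag set."""
        if self.processed is None:
            raise ValueError("run apply_detection_filters first")
        keep = self.processed[self.processed].index
        return ProteinQuantTable(
            self.ratios.loc[keep],
            self.n_peptides.loc[keep],
            self.heavy_detected.loc[keep],
            self.stage1_pass.loc[keep],
            self.processed.loc[keep],
            dict(self.filter_log),
        )

    def to_tsv(self, path: str | Path, header_comment: str | None = None) -> None:
        flat = self.ratios.copy()
        flat.columns = [f"ratio_LH {tp} r{rep}" for tp, rep in flat.columns]
        npep = self.n_peptides.copy()
        npep.columns = [f"n_peptides {tp} r{rep}" for tp, rep in npep.columns]
        out = pd.concat([flat, npep], axis=1)
        if self.stage1_pass is not None:
            out["stage1_pass"] = self.stage1_pass
        if self.processed is not None:
            out["processed"] = self.processed
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            out.to_csv(fh, sep="\t", index_label="gene")


def aggregate_protein_ratios(
    table: pd.DataFrame, min_peptides_quant: int = 2
) -> ProteinQuantTable:
    """Median peptide ratio per (gene, timepoint, replicate).

    The median runs over all non-missing peptide ratios (even count:
    mean of the middle two). A protein value is retained only when
    represented by >= ``min_peptides_quant`` distinct peptides in that
    sample; otherwise the quantity is missing — the "two or more
    quantitated peptides" detection rule. Expects the singleton-masked
    peptide table.
    """
    grp = table.groupby(["gene", "timepoint", "replicate"])
    med = grp["ratio_LH"].median()
    n_pep = (
        table[table["ratio_LH"].notna()]
        .groupby(["gene", "timepoint", "replicate"])["peptide_key"]
        .nunique()
    )
    n_heavy = (
        table[table["heavy_quant"]]
        .groupby(["gene", "timepoint", "replicate"])["peptide_key"]
        .nunique()
    )

    def to_wide(s: pd.Series, fill=np.nan) -> pd.DataFrame:
        wide = s.unstack(["timepoint", "replicate"])
        return wide.sort_index(axis=1).sort_index()

    ratios = to_wide(med)
    n_peptides = to_wide(n_pep).reindex(ratios.index).reindex(columns=ratios.columns)
    n_peptides = n_peptides.fillna(0).astype(int)
    heavy = to_wide(n_heavy).reindex(ratios.index).reindex(columns=ratios.columns)
    heavy_detected = heavy.fillna(0).astype(int) >= min_peptides_quant
    # detection rule: quantity only where backed by >= min distinct peptides
    ratios = ratios.where(n_peptides >= min_peptides_quant)
    return ProteinQuantTable(ratios, n_peptides, heavy_detected)


def aggregate_protein_intensities(
    matrix: FeatureIntensityMatrix, min_peptides: int = 2
) -> pd.DataFrame:
    """Protein-level absolute intensities: per-gene median over peptides.

    A protein quantity is kept for a sample only when represented by
    >= ``min_peptides`` distinct peptides there (otherwise NA) — the
    detection definition used for the detection-count and replicate-
    correlation metrics. Returns genes x sample-units on the input scale.
    """
    vals = matrix.values.copy()
    vals["gene"] = matrix.features["gene"]
    vals["pep"] = [peptide_key(f) for f in vals.index]
    med = vals.groupby("gene").median(numeric_only=True)
    long = vals.melt(id_vars=["gene", "pep"], var_name="sample", value_name="x")
    npep = (
        long[long["x"].notna()]
        .groupby(["gene", "sample"])["pep"]
        .nunique()
        .unstack("sample")
        .reindex(index=med.index, columns=med.columns)
        .fillna(0)
    )
    return med.where(npep >= min_peptides)


def apply_detection_filters(
    pq: ProteinQuantTable,
    design: SampleDesign,
    min_peptides: int = 2,
    min_reps: int = 2,
    n_reps: int = 3,
) -> ProteinQuantTable:
    """Fill stage-1 and processed flags; log casualty counts.

    Stage 1: non-missing protein ratios in >= ``min_reps`` of ``n_reps``
    replicates at ANY time point. Stage 2 ("processed dataset"):
    additionally >= ``min_peptides`` distinct peptides somewhere and
    heavy-control detection in >= ``min_reps`` replicates at BOTH time
    points.
    """
    tps = design.timepoint_replicates()
    if len(tps) < 2:
        raise DesignError("processed filter needs heavy controls at two time points")
    for tp in tps:
        if tp not in pq.ratios.columns.get_level_values(0):
            raise DesignError(f"protein table lacks time point {tp!r}")

    per_tp_quant = {
        tp: pq.ratios[tp].notna().sum(axis=1) for tp in tps
    }
    stage1 = pd.concat(
        [cnt >= min_reps for cnt in per_tp_quant.values()], axis=1
    ).any(axis=1)

    enough_peptides = pq.n_peptides.max(axis=1) >= min_peptides
    heavy_both = pd.concat(
        [pq.heavy_detected[tp].sum(axis=1) >= min_reps for tp in tps], axis=1
    ).all(axis=1)
    processed = stage1 & enough_peptides & heavy_both

    n = len(pq.genes)
    log = {
        "genes_total": int(n),
        "stage1_any_timepoint": int(stage1.sum()),
        "stage1_removed": int(n - stage1.sum()),
        "stage2_processed": int(processed.sum()),
        "stage2_removed": int(stage1.sum() - processed.sum()),
        "min_peptides": min_peptides,
        "min_reps": min_reps,
        "n_reps": n_reps,
    }
    logger.info(
        "detection filters: %d genes -> stage1 %d -> processed %d",
        n, log["stage1_any_timepoint"], log["stage2_processed"],
    )
    return ProteinQuantTable(
        pq.ratios.copy(), pq.n_peptides.copy(), pq.heavy_detected.copy(),
        stage1, processed, log,
    )
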