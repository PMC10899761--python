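"""End-to-end pipeline runs and the DDA-vs-DIA comparison report.

``run_pipeline`` executes ingest -> normalize -> quantify -> stats
(-> impute) -> metrics for one acquisition arm and writes a run
directory of TSV tables plus a ``summary.json`` recording gene counts
surviving each stage, the percentile thresholds, and a config
fingerprint. Runs are deterministic: identical config + inputs + seed
give byte-identical outputs (timestamps live only in the log).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics as metrics_mod
from .design import SampleDesign
from .errors import ComparisonError, ConfigError
from .impute import ImputationConfig, impute
from .ingest import (
    build_intensity_matrix,
    read_diann_report,
    read_maxquant_peptides,
    read_maxquant_protein_groups,
)
from .matrix import FeatureIntensityMatrix
from .normalize import NormalizationConfig, normalize, normalize_scalar
from .quantify import (
    ProteinQuantTable,
    aggregate_protein_intensities,
    aggregate_protein_ratios,
    apply_detection_filters,
    compute_peptide_ratios,
    mask_single_peptide_quantitations,
)
from .stats import (
    DifferentialConfig,
    EnrichmentConfig,
    crosslink_enrichment,
    differential_association,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    acquisition: str  # "DDA" | "DIA"
    input_path: str
    design_path: str
    out_dir: str
    normalization: NormalizationConfig = field(default_factory=NormalizationConfig)
    min_peptides: int = 2
    min_reps: int = 2
    n_reps: int = 3
    alpha: float = 0.05
    bh_alpha: float = 0.05
    enrichment_min_fc: float = 1.5
    cl_intensities_path: str | None = None  # protein x sample TSV; CL_*/nonCL_* columns
    imputation: ImputationConfig | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.acquisition not in ("DDA", "DIA"):
            raise ConfigError(f"acquisition must be DDA or DIA, got {self.acquisition!r}")

    def fingerprint(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")  # where results land does not change what they are
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_design(path: str) -> SampleDesign:
    if str(path).endswith((".yaml", ".yml")):
        return SampleDesign.from_yaml(path)
    return SampleDesign.from_tsv(path)


def _ingest(config: PipelineConfig, design: SampleDesign) -> FeatureIntensityMatrix:
    if config.acquisition == "DIA":
        records = read_diann_report(config.input_path)
    else:
        pep = read_maxquant_peptides(config.input_path)
        records = pep.rename(columns={"experiment": "run_id"})
        records["feature_id"] = records["peptide_id"]
    return build_intensity_matrix(records, design)


def _enrichment_from_tsv(path: str, config: PipelineConfig) -> pd.DataFrame:
    """CL vs non-CL classification from a protein-intensity TSV.

    Columns starting ``CL_`` are crosslinked samples, ``nonCL_`` the
    controls. Intensities are log2-transformed and mean-normalized
    before testing, as the enrichment rule specifies.
    """
    mat = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    cl_cols = [c for c in mat.columns if c.startswith("CL_")]
    noncl_cols = [c for c in mat.columns if c.startswith("nonCL_")]
    if not cl_cols or not noncl_cols:
        raise ConfigError(f"{path}: need CL_* and nonCL_* sample columns")
    log2 = np.log2(mat.where(mat > 0))
    fim = FeatureIntensityMatrix(
        log2,
        pd.DataFrame({"gene": log2.index, "protein_ids": ""}, index=log2.index),
        "log2",
    )
    normed = normalize_scalar(fim, "mean").values
    return crosslink_enrichment(
        normed[cl_cols],
        normed[noncl_cols],
        EnrichmentConfig(alpha=config.bh_alpha, min_fc=config.enrichment_min_fc),
    )


def run_pipeline(config: PipelineConfig) -> Path:
    """Run one acquisition arm end to end; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = f"config_hash={config.fingerprint()}"

    design = _load_design(config.design_path)
    raw = _ingest(config, design)
    logger.info("ingested %d features x %d samples", raw.n_features, len(raw.samples))

    normed = normalize(raw, config.normalization)
    normed.to_tsv(out / "normalized_matrix.tsv", tag)

    table = compute_peptide_ratios(normed, design)
    masked = mask_single_peptide_quantitations(table)
    pq = aggregate_protein_ratios(masked, config.min_peptides)
    pq = apply_detection_filters(
        pq, design, config.min_peptides, config.min_reps, config.n_reps
    )
    pq.to_tsv(out / "protein_quant.tsv", tag)

    enrichment = None
    if config.cl_intensities_path:
        enrichment = _enrichment_from_tsv(config.cl_intensities_path, config)
        with open(out / "enrichment.tsv", "w") as fh:
            fh.write(f"# {tag}\n")
            enrichment.to_csv(fh, sep="\t")

    processed = pq.processed_view()
    diff = differential_association(
        processed,
        DifferentialConfig(
            alpha=config.alpha, bh_alpha=config.bh_alpha, min_reps=config.min_reps
        ),
        enrichment,
    )
    with open(out / "differential.tsv", "w") as fh:
        fh.write(f"# {tag}\n")
        diff.to_csv(fh, sep="\t")

    imputed_summary = None
    if config.imputation is not None:
        imputed_summary = _run_imputed(
            pq, config, enrichment, out, tag
        )

    # metrics --------------------------------------------------------
    raw_log2 = raw.to_log2()
    prot_int = aggregate_protein_intensities(raw_log2, config.min_peptides)
    units = design.sample_units()
    heavy_cols = [s for s in prot_int.columns if units.loc[s, "channel"] == "heavy"]
    rep_corr = {}
    for tp in design.timepoint_replicates():
        cols = [s for s in heavy_cols if units.loc[s, "timepoint"] == tp]
        if len(cols) >= 2:
            rep_corr[tp] = metrics_mod.replicate_correlation(prot_int, cols)
    maxsd = metrics_mod.max_replicate_sd(processed)
    cond_cols = {
        f"{tp}_{ch}": [
            s for s in prot_int.columns
            if units.loc[s, "timepoint"] == tp and units.loc[s, "channel"] == ch
        ]
        for tp in design.timepoint_replicates()
        for ch in ("light", "heavy")
    }
    detect = metrics_mod.detection_and_missingness_summary(prot_int, cond_cols)

    summary = {
        "acquisition": config.acquisition,
        "config_hash": config.fingerprint(),
        "seed": config.seed,
        "n_features": raw.n_features,
        "n_genes": int(len(pq.genes)),
        "filter_log": pq.filter_log,
        "n_processed": int(pq.processed.sum()),
        "n_tested": diff.attrs["n_tested"],
        "n_excluded_insufficient_quant": diff.attrs["n_excluded"],
        "p10": diff.attrs["p10"],
        "p90": diff.attrs["p90"],
        "n_significant_primary": int(diff["significant_primary"].sum()),
        "n_significant_bh": int(diff["significant_bh"].sum()),
        "median_max_sd": float(maxsd.median()),
        "mean_max_sd": float(maxsd.mean()),
        "replicate_correlation": rep_corr,
        "detection": detect,
        "maxsd_scale": "linear_ratio",
    }
    if enrichment is not None:
        summary["n_enriched"] = int(enrichment["enriched"].sum())
        summary["n_exclusive_to_cl"] = int(enrichment["exclusive_to_cl"].sum())
        summary["n_significant_rbp"] = int(diff["significant_rbp"].sum())
    if imputed_summary:
        summary["imputation"] = imputed_summary
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, sort_keys=True, indent=1, default=_json_default)
        fh.write("\n")
    maxsd.to_csv(out / "max_replicate_sd.tsv", sep="\t")
    return out


def _run_imputed(pq, config, enrichment, out: Path, tag: str) -> dict:
    """Imputation branch: fill stage-1 genes' ratio matrix, re-test.

    Input is the stage-1 gene set (>= 2 quantitations at either time
    point). Genes with <= 1 quantitation at a time point before
    imputation are flagged not robust and excluded from significance
    calls after random-forest imputation.
    """
    keep = pq.stage1_pass[pq.stage1_pass].index
    ratios = pq.ratios.loc[keep]
    log2r = np.log2(ratios)
    flat = log2r.copy()
    flat.columns = [f"{tp}|{rep}" for tp, rep in log2r.columns]
    imputed_flat, mask = impute(flat, config.imputation, log_scale=True)
    imputed = imputed_flat.copy()
    imputed.columns = log2r.columns

    not_robust = pd.Series(False, index=keep)
    if config.imputation.method == "random_forest":
        for tp in pq.timepoints():
            not_robust |= log2r[tp].notna().sum(axis=1) <= 1

    pq_imp = ProteinQuantTable(
        np.power(2.0, imputed),
        pq.n_peptides.loc[keep],
        pq.heavy_detected.loc[keep],
    )
    diff = differential_association(
        pq_imp,
        DifferentialConfig(alpha=config.alpha, bh_alpha=config.bh_alpha,
                           min_reps=config.min_reps),
        enrichment,
    )
    diff["prediction_not_robust"] = not_robust.reindex(diff.index).fillna(False)
    flagged = diff["prediction_not_robust"]
    diff.loc[flagged, ["significant_primary", "significant_bh"]] = False
    with open(out / f"differential_imputed_{config.imputation.method}.tsv", "w") as fh:
        fh.write(f"# {tag}\n")
        diff.to_csv(fh, sep="\t")
    mask.columns = [c.replace("|", " r") for c in mask.columns]
    with open(out / "imputed_mask.tsv", "w") as fh:
        fh.write(f"# {tag}\n")
        mask.to_csv(fh, sep="\t")
    return {
        "method": config.imputation.method,
        "n_imputed_cells": int(mask.to_numpy().sum()),
        "n_not_robust": int(flagged.sum()),
        "n_significant_primary": int(diff["significant_primary"].sum()),
        "n_significant_bh": int(diff["significant_bh"].sum()),
    }


def _json_default(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, float) and np.isnan(x):
        return None
    raise TypeError(f"not JSON serializable: {type(x)}")


# ----------------------------------------------------------------------
def _read_differential(run_dir: Path) -> pd.DataFrame:
    return pd.read_csv(run_dir / "differential.tsv", sep="\t", index_col="gene",
                       comment="#")


def compare_acquisitions(run_dir_a: str | Path, run_dir_b: str | Path) -> dict:
    """Compare two completed runs (conventionally DDA vs DIA).

    Reports detected/analyzable counts per arm, significant-gene counts
    and overlap, significant-in-both genes with opposite fold-change
    sign, median MaxSD per arm, and cross-acquisition R^2 of log2FC at
    four restriction levels: all shared tested genes; crosslink-enriched
    in both; significant in either; significant in both.
    """
    a_dir, b_dir = Path(run_dir_a), Path(run_dir_b)
    with open(a_dir / "summary.json") as fh:
        sum_a = json.load(fh)
    with open(b_dir / "summary.json") as fh:
        sum_b = json.load(fh)
    diff_a, diff_b = _read_differential(a_dir), _read_differential(b_dir)

    tps_a = set(k.split("_")[0] for k in sum_a["detection"])
    tps_b = set(k.split("_")[0] for k in sum_b["detection"])
    if tps_a != tps_b:
        raise ComparisonError(f"mismatched time points: {tps_a} vs {tps_b}")

    shared = diff_a.index.intersection(diff_b.index)
    fc_a, fc_b = diff_a["log2fc"], diff_b["log2fc"]
    sig_a = diff_a.index[diff_a["significant_primary"]]
    sig_b = diff_b.index[diff_b["significant_primary"]]
    sig_both = sig_a.intersection(sig_b)
    conflicts = [
        g for g in sig_both
        if np.sign(fc_a[g]) != np.sign(fc_b[g]) and fc_a[g] != 0 and fc_b[g] != 0
    ]

    def r2(genes) -> float | None:
        try:
            return metrics_mod.cross_acquisition_fc_correlation(fc_a, fc_b, genes)
        except ValueError:
            return None

    # MaxSD restricted to proteins quantified in both arms isolates
    # acquisition precision from detection-range differences
    sd_a = pd.read_csv(a_dir / "max_replicate_sd.tsv", sep="\t", index_col=0).iloc[:, 0]
    sd_b = pd.read_csv(b_dir / "max_replicate_sd.tsv", sep="\t", index_col=0).iloc[:, 0]
    shared_sd = sd_a.dropna().index.intersection(sd_b.dropna().index)

    restrictions = {"all_shared_tested": r2(shared)}
    if "crosslink_enriched" in diff_a.columns and "crosslink_enriched" in diff_b.columns:
        enr = shared[
            diff_a.loc[shared, "crosslink_enriched"]
            & diff_b.loc[shared, "crosslink_enriched"]
        ]
        restrictions["crosslink_enriched_both"] = r2(enr)
    restrictions["significant_in_either"] = r2(sig_a.union(sig_b))
    restrictions["significant_in_both"] = r2(sig_both)

    report = {
        "arm_a": {
            "acquisition": sum_a["acquisition"],
            "n_tested": sum_a["n_tested"],
            "n_processed": sum_a["n_processed"],
            "n_significant": int(len(sig_a)),
            "median_max_sd": sum_a["median_max_sd"],
            "detection": sum_a["detection"],
        },
        "arm_b": {
            "acquisition": sum_b["acquisition"],
            "n_tested": sum_b["n_tested"],
            "n_processed": sum_b["n_processed"],
            "n_significant": int(len(sig_b)),
            "median_max_sd": sum_b["median_max_sd"],
            "detection": sum_b["detection"],
        },
        "median_max_sd_shared": {
            "arm_a": float(sd_a.loc[shared_sd].median()) if len(shared_sd) else None,
            "arm_b": float(sd_b.loc[shared_sd].median()) if len(shared_sd) else None,
            "n_shared": int(len(shared_sd)),
        },
        "n_shared_tested": int(len(shared)),
        "n_significant_both": int(len(sig_both)),
        "n_sign_conflicts": len(conflicts),
        "sign_conflict_genes": sorted(conflicts),
        "log2fc_r2": restrictions,
    }
    return report


def write_comparison(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, sort_keys=True, indent=1, default=_json_default)
        fh.write("\n")
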