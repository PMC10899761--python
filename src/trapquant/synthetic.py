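"""Ground-truthed SILAC experiment simulator.

Emulates the layout of the arsenite TRAPP study — two treatment time
points (10 min, 1 h) x three biological replicates, light = treated and
heavy = mock channels in every run, plus a crosslinked vs
non-crosslinked arm (4 vs 4 samples) — and writes the results in the
DIA-NN and MaxQuant table dialects so the whole pipeline is exercisable
without any deposited raw data.

Generative model (all effects on log2 scale)::

    heavy  = baseline_protein + peptide_offset + replicate_effect + eps_H
    light  = heavy_noiseless  + log2(true L/H ratio) + eps_L

The replicate effect is shared by both channels of a run and therefore
cancels in the light/heavy ratio; ratio scatter comes from the
per-channel noise ``eps`` (sd ``channel_sd_log2`` per channel, hence
sqrt(2) x that per peptide ratio). Missingness is intensity-dependent
(logistic detection probability, midpoint/slope configurable — MNAR)
plus a uniform MCAR rate. The DDA arm sees a subset of peptides, a
higher detection midpoint and noisier channels than the DIA arm, which
reproduces the qualitative DDA/DIA contrast: DIA detects more proteins
(including partially-missing low-abundance ones) with lower ratio
scatter.

Defaults are the package's standing description of the emulated study:
baseline log2 mean 17, sd 2 (anchored to the reported intensity
medians), effect size 1 log2 unit on 10% of proteins, per-channel noise
0.15 log2 units, three replicates. They are generator settings, not
claims about the real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .design import SampleDesign
from .errors import ConfigError
from .quantify import ProteinQuantTable

_AA = "ACDEFGHILMNPQSTVWY"  # no K/R except the tryptic terminus


@dataclass
class SimulationConfig:
    n_proteins: int = 1000
    peptides_per_protein_mean: float = 4.0  # shifted geometric
    peptides_per_protein_min: int = 1
    baseline_log2_mean: float = 17.0
    baseline_log2_sd: float = 2.0
    peptide_offset_sd_log2: float = 1.0
    fraction_changed: float = 0.1
    effect_log2: float = 1.0
    replicate_sd_log2: float = 0.2
    channel_sd_log2: float = 0.15
    n_replicates: int = 3
    # missingness: DIA has a low midpoint with a wide transition zone
    # (detects far down, but marginal ids drop in and out), DDA a higher,
    # sharper cutoff -- together these reproduce the observed pattern of
    # more detected proteins yet more missingness-among-detected in DIA
    mnar_midpoint_log2: float = 14.0
    mnar_slope: float = 0.3
    mcar_rate: float = 0.02
    # crosslink arm
    fraction_background_binders: float = 0.3
    background_cl_fc: float = 1.0   # CL/non-CL fold change of silica background
    rbp_cl_fc: float = 8.0          # CL/non-CL fold change of true RBPs
    # acquisition contrast
    dia_charge_expansion: float = 0.4   # P(second charge state per peptide)
    dda_peptide_fraction: float = 0.75  # peptides visible to DDA
    dda_mnar_midpoint_log2: float = 15.5
    dda_mnar_slope: float = 3.0
    dda_channel_sd_scale: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fraction_changed", "mcar_rate", "fraction_background_binders",
                     "dia_charge_expansion", "dda_peptide_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.n_proteins < 1 or self.n_replicates < 1:
            raise ConfigError("n_proteins and n_replicates must be >= 1")
        if self.peptides_per_protein_min < 1:
            raise ConfigError("peptides_per_protein_min must be >= 1")
        if self.peptides_per_protein_mean < self.peptides_per_protein_min:
            raise ConfigError("peptides_per_protein_mean must be >= the minimum")
        if self.seed is None:
            raise ConfigError("seed is mandatory")


@dataclass
class SimulationResult:
    truth: pd.DataFrame = field(repr=False)
    dia_records: pd.DataFrame = field(repr=False)
    dda_records: pd.DataFrame = field(repr=False)
    dia_design: SampleDesign = field(repr=False)
    dda_design: SampleDesign = field(repr=False)
    cl_intensities: pd.DataFrame = field(repr=False)      # genes x samples, linear
    cl_sample_info: pd.DataFrame = field(repr=False)      # sample -> crosslinked, channel
    expected_missing_fraction: dict = field(default_factory=dict)
    config: SimulationConfig | None = None


# ----------------------------------------------------------------------
def _peptide_sequence(prot: int, pep: int) -> str:
    """Deterministic tryptic-looking sequence, unique per (protein, peptide).

    Digits map injectively onto ten residues and 'Y' separates the two
    indices, so no two (protein, peptide) pairs collide.
    """
    enc = lambda k: "".join(_AA[int(c)] for c in str(k))
    terminus = "K" if (prot + pep) % 2 == 0 else "R"
    return f"PE{enc(prot)}Y{enc(pep)}TIDE{terminus}"


def _make_design(acquisition: str, n_replicates: int) -> SampleDesign:
    rows = []
    for tp in ("t10min", "t1h"):
        for rep in range(1, n_replicates + 1):
            rows.append(
                {
                    "run_id": f"{acquisition}_{tp}_r{rep}",
                    "acquisition": acquisition,
                    "timepoint": tp,
                    "replicate": rep,
                    "light_condition": "arsenite",
                    "heavy_condition": "mock",
                    "crosslinked": True,
                }
            )
    return SampleDesign(pd.DataFrame(rows))


def simulate_experiment(config: SimulationConfig) -> SimulationResult:
    """Draw one complete synthetic experiment (all three arms).

    Fully reproducible from ``config.seed``; identical configs give
    byte-identical outputs.
    """
    rng = np.random.default_rng(config.seed)

    n = config.n_proteins
    genes = np.array([f"GENE{i:05d}" for i in range(n)])
    prot_ids = np.array([f"P{i:06d}" for i in range(n)])
    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n)

    n_changed = int(round(config.fraction_changed * n))
    changed_idx = rng.choice(n, size=n_changed, replace=False)
    changed = np.zeros(n, dtype=bool)
    changed[changed_idx] = True
    direction = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    log2_ratio_t10 = np.zeros(n)
    log2_ratio_t1h = np.where(changed, direction * config.effect_log2, 0.0)

    background = rng.random(n) < config.fraction_background_binders
    rbp = ~background

    truth = pd.DataFrame(
        {
            "gene": genes,
            "protein_ids": prot_ids,
            "baseline_log2": baseline,
            "changed": changed,
            "rbp": rbp,
            "background_binder": background,
            "true_ratio_t10min": np.power(2.0, log2_ratio_t10),
            "true_ratio_t1h": np.power(2.0, log2_ratio_t1h),
            "true_log2fc": log2_ratio_t1h - log2_ratio_t10,
        }
    ).set_index("gene")

    # peptide layer -----------------------------------------------------
    # shifted geometric: min + Geom - 1, with the mean pinned to config
    p_geom = 1.0 / (config.peptides_per_protein_mean - config.peptides_per_protein_min + 1)
    n_pep = config.peptides_per_protein_min + rng.geometric(p_geom, size=n) - 1
    prot_of_pep = np.repeat(np.arange(n), n_pep)
    pep_rank = np.concatenate([np.arange(k) for k in n_pep])
    pep_offset = rng.normal(0.0, config.peptide_offset_sd_log2, len(prot_of_pep))
    pep_seq = np.array(
        [_peptide_sequence(p, j) for p, j in zip(prot_of_pep, pep_rank)]
    )
    dda_visible = rng.random(len(prot_of_pep)) < config.dda_peptide_fraction
    extra_charge = rng.random(len(prot_of_pep)) < config.dia_charge_expansion

    # replicate effects shared by the two channels of a run
    tps = ("t10min", "t1h")
    reps = range(1, config.n_replicates + 1)
    rep_effect = {
        (tp, r): rng.normal(0.0, config.replicate_sd_log2, n)
        for tp in tps for r in reps
    }
    tp_log_ratio = {"t10min": log2_ratio_t10, "t1h": log2_ratio_t1h}

    def draw_arm(acquisition: str) -> tuple[pd.DataFrame, dict]:
        is_dda = acquisition == "DDA"
        keep_pep = dda_visible if is_dda else np.ones(len(prot_of_pep), bool)
        pidx = prot_of_pep[keep_pep]
        offs = pep_offset[keep_pep]
        seqs = pep_seq[keep_pep]
        midpoint = config.dda_mnar_midpoint_log2 if is_dda else config.mnar_midpoint_log2
        slope = config.dda_mnar_slope if is_dda else config.mnar_slope
        ch_sd = config.channel_sd_log2 * (config.dda_channel_sd_scale if is_dda else 1.0)

        # charge states: DDA sees one per peptide; DIA may add charge 3
        charges = [np.full(len(pidx), 2)]
        blocks = [np.arange(len(pidx))]
        if not is_dda:
            ext = np.flatnonzero(extra_charge[keep_pep])
            charges.append(np.full(len(ext), 3))
            blocks.append(ext)
        rows = []
        exp_missing = []
        for tp in tps:
            for r in reps:
                run = f"{acquisition}_{tp}_r{r}"
                base_run = baseline[pidx] + offs + rep_effect[(tp, r)][pidx]
                for block, charge in zip(blocks, charges):
                    shift = -1.0 if charge[0] == 3 else 0.0  # minor charge state dimmer
                    clean = base_run[block] + shift
                    for channel in ("heavy", "light"):
                        x = clean + rng.normal(0.0, ch_sd, len(block))
                        if channel == "light":
                            x = x + tp_log_ratio[tp][pidx[block]]
                        p_det = expit(slope * (x - midpoint)) * (1 - config.mcar_rate)
                        detected = rng.random(len(block)) < p_det
                        exp_missing.append(1.0 - p_det)
                        rows.append(
                            pd.DataFrame(
                                {
                                    "run_id": run,
                                    "protein_ids": prot_ids[pidx[block]],
                                    "gene": genes[pidx[block]],
                                    "sequence": seqs[block],
                                    "charge": charge,
                                    "channel": channel,
                                    "log2_intensity": np.where(detected, x, np.nan),
                                }
                            )
                        )
        arm = pd.concat(rows, ignore_index=True)
        n_candidates = len(arm)
        arm = arm[arm["log2_intensity"].notna()].reset_index(drop=True)
        arm["intensity"] = np.power(2.0, arm["log2_intensity"])
        info = {
            "expected_missing_fraction": float(np.mean(np.concatenate(exp_missing))),
            "realized_missing_fraction": 1.0 - len(arm) / n_candidates,
        }
        return arm, info

    dia_records, dia_info = draw_arm("DIA")
    dda_records, dda_info = draw_arm("DDA")
    dia_records["feature_id"] = (
        dia_records["protein_ids"] + "|" + dia_records["gene"] + "|"
        + dia_records["sequence"] + dia_records["charge"].astype(str)
    )
    dda_records["feature_id"] = dda_records["sequence"]
    dia_records["q_value"] = rng.uniform(0.0, 0.009, len(dia_records))
    dia_records["translated_q"] = rng.uniform(0.0, 0.009, len(dia_records))

    # crosslink vs non-crosslink arm (protein level, 2 runs x 2 channels/side)
    cl_rows = []
    cl_mat = pd.DataFrame(index=truth.index)
    cl_log2fc = np.where(rbp, np.log2(config.rbp_cl_fc), np.log2(config.background_cl_fc))
    for crosslinked in (True, False):
        for run in (1, 2):
            for channel in ("L", "H"):
                name = f"{'CL' if crosslinked else 'nonCL'}_r{run}{channel}"
                x = baseline + rng.normal(0.0, config.replicate_sd_log2, n) \
                    + rng.normal(0.0, config.channel_sd_log2, n)
                if crosslinked:
                    x = x + cl_log2fc
                p_det = expit(config.mnar_slope * (x - config.mnar_midpoint_log2)) \
                    * (1 - config.mcar_rate)
                detected = rng.random(n) < p_det
                cl_rows.append(
                    {"sample": name, "crosslinked": crosslinked, "channel": channel}
                )
                cl_mat[name] = np.where(detected, np.power(2.0, x), np.nan)

    return SimulationResult(
        truth=truth,
        dia_records=dia_records,
        dda_records=dda_records,
        dia_design=_make_design("DIA", config.n_replicates),
        dda_design=_make_design("DDA", config.n_replicates),
        cl_intensities=cl_mat,
        cl_sample_info=pd.DataFrame(cl_rows).set_index("sample"),
        expected_missing_fraction={"DIA": dia_info, "DDA": dda_info},
        config=config,
    )


# ----------------------------------------------------------------------
def simulate_protein_ratio_table(
    n_proteins: int = 2000,
    n_replicates: int = 3,
    replicate_sd_log2: float = 0.2,
    fraction_changed: float = 0.0,
    effect_log2: float = 1.0,
    seed: int = 0,
) -> tuple[ProteinQuantTable, pd.DataFrame]:
    """Protein-level ratio table for statistics harnesses.

    Skips the peptide layer: each (gene, timepoint, replicate) cell is a
    light/heavy ratio 2**(true log2 ratio + N(0, replicate_sd_log2)).
    All cells are complete, backed by nominally 4 peptides, heavy
    detected everywhere. Returns (table, truth frame).
    """
    rng = np.random.default_rng(seed)
    genes = [f"GENE{i:05d}" for i in range(n_proteins)]
    n_changed = int(round(fraction_changed * n_proteins))
    changed = np.zeros(n_proteins, dtype=bool)
    changed[rng.choice(n_proteins, n_changed, replace=False)] = True
    direction = np.where(rng.random(n_proteins) < 0.5, 1.0, -1.0)
    true_fc = np.where(changed, direction * effect_log2, 0.0)

    cols = pd.MultiIndex.from_product(
        [("t10min", "t1h"), range(1, n_replicates + 1)],
        names=["timepoint", "replicate"],
    )
    log2r = pd.DataFrame(
        rng.normal(0.0, replicate_sd_log2, (n_proteins, len(cols))),
        index=pd.Index(genes, name="gene"),
        columns=cols,
    )
    log2r.loc[:, "t1h"] = log2r["t1h"].to_numpy() + true_fc[:, None]
    ratios = np.power(2.0, log2r)
    n_pep = pd.DataFrame(4, index=ratios.index, columns=cols)
    heavy = pd.DataFrame(True, index=ratios.index, columns=cols)
    truth = pd.DataFrame(
        {"changed": changed, "true_log2fc": true_fc},
        index=pd.Index(genes, name="gene"),
    )
    return ProteinQuantTable(ratios, n_pep, heavy), truth


# ----------------------------------------------------------------------
# dialect writers
# ----------------------------------------------------------------------
def _tagged_precursor_id(sequence: str, charge: int, channel: str) -> str:
    letter = sequence[-1]  # tryptic terminus K or R
    hl = "H" if channel == "heavy" else "L"
    return f"{sequence}(SILAC-{letter}-{hl}){charge}"


def write_diann_like(records: pd.DataFrame, path: str | Path) -> None:
    """Write records in the DIA-NN Report.tsv dialect.

    SILAC channel tags are re-inserted into Precursor.Id; the result is
    readable by :func:`trapquant.ingest.read_diann_report`.
    """
    out = pd.DataFrame(
        {
            "Run": records["run_id"],
            "Protein.Ids": records["protein_ids"],
            "Genes": records["gene"],
            "Precursor.Id": [
                _tagged_precursor_id(s, c, ch)
                for s, c, ch in zip(records["sequence"], records["charge"], records["channel"])
            ],
            "Precursor.Translated": records["intensity"],
            "Q.Value": records["q_value"],
            "Translated.Q.Value": records["translated_q"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def write_maxquant_like(
    records: pd.DataFrame,
    path_peptides: str | Path,
    path_proteingroups: str | Path,
    inject_decoys: bool = True,
) -> None:
    """Write records in the MaxQuant peptides.txt / proteinGroups.txt dialects.

    peptides.txt gets per-experiment ``Intensity L/H <exp>`` columns and
    a unique flag; proteinGroups.txt carries normalized H/L ratios
    (median peptide H/L per gene per experiment) with empty
    contaminant/reverse flags. With ``inject_decoys``, one reverse, one
    contaminant and one keratin row are appended to proteinGroups.txt
    and one non-unique peptide to peptides.txt, so reader-side removal
    rules are exercised.
    """
    rec = records.copy()
    rec["experiment"] = rec["run_id"]  # experiment names double as run ids
    rec["col"] = (
        "Intensity "
        + rec["channel"].map({"heavy": "H", "light": "L"})
        + " "
        + rec["experiment"]
    )
    wide = rec.pivot_table(
        index=["sequence", "gene", "protein_ids"],
        columns="col",
        values="intensity",
        aggfunc="first",
    ).reset_index()
    wide = wide.rename(
        columns={"sequence": "Sequence", "gene": "Gene names", "protein_ids": "Proteins"}
    )
    wide["Unique (Groups)"] = "yes"
    int_cols = sorted(c for c in wide.columns if c.startswith("Intensity "))
    pep = wide[["Sequence", "Gene names", "Proteins", "Unique (Groups)"] + int_cols]
    pep = pep.sort_values("Sequence").reset_index(drop=True)
    if inject_decoys:
        shared = {c: 1000.0 for c in int_cols}
        pep = pd.concat(
            [pep, pd.DataFrame([{"Sequence": "SHAREDPEPTIDEK", "Gene names": "GENE00000",
                                 "Proteins": "P000000;P000001",
                                 "Unique (Groups)": "no", **shared}])],
            ignore_index=True,
        )
    pep.to_csv(path_peptides, sep="\t", index=False)

    # protein groups: median peptide H/L per gene per experiment
    hl = rec.pivot_table(
        index=["sequence", "gene", "protein_ids", "experiment"],
        columns="channel",
        values="intensity",
        aggfunc="first",
    ).reset_index()
    for ch in ("heavy", "light"):
        if ch not in hl.columns:
            hl[ch] = np.nan
    hl["ratio_hl"] = hl["heavy"] / hl["light"]
    pg = (
        hl.groupby(["gene", "protein_ids", "experiment"])["ratio_hl"]
        .median()
        .unstack("experiment")
    )
    pg.columns = [f"Ratio H/L normalized {c}" for c in pg.columns]
    pg = pg.reset_index().rename(
        columns={"gene": "Gene names", "protein_ids": "Majority protein IDs"}
    )
    pg["Reverse"] = ""
    pg["Potential contaminant"] = ""
    pg = pg.sort_values("Gene names").reset_index(drop=True)
    if inject_decoys:
        ratio_cols = [c for c in pg.columns if c.startswith("Ratio")]
        decoys = [
            {"Gene names": "REVDECOY", "Majority protein IDs": "REV__P999999",
             "Reverse": "+", "Potential contaminant": "",
             **{c: 1.0 for c in ratio_cols}},
            {"Gene names": "CONDECOY", "Majority protein IDs": "CON__P999998",
             "Reverse": "", "Potential contaminant": "+",
             **{c: 1.0 for c in ratio_cols}},
            {"Gene names": "KRT1", "Majority protein IDs": "P999997",
             "Reverse": "", "Potential contaminant": "",
             **{c: 1.0 for c in ratio_cols}},
        ]
        pg = pd.concat([pg, pd.DataFrame(decoys)], ignore_index=True)
    pg.to_csv(path_proteingroups, sep="\t", index=False)


def write_truth(result: SimulationResult, path: str | Path) -> None:
    result.truth.to_csv(path, sep="\t")


def config_dict(config: SimulationConfig) -> dict:
    return asdict(config)
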