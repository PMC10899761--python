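# trapquant

Quantitation of RNA-bound proteomes from SILAC mass-spectrometry data.

RNA-interactome capture experiments (e.g. TRAPP: UV-crosslink cells,
capture total RNA on silica, digest and identify the co-purified
proteins) have no internal reference for absolute quantitation, so
recovery is measured *relatively* with SILAC: "light" cells are treated
(here: sodium arsenite), "heavy" ¹³C₆-Lys/Arg cells are mock-treated,
lysates are mixed 1:1 and the light/heavy (L/H) intensity ratio of each
peptide reports the treatment effect on that protein's RNA association.
Such samples can be acquired by data-dependent (DDA, MaxQuant output)
or data-independent (DIA, DIA-NN output) MS; `trapquant` ingests both
dialects, runs an identical downstream quantitation chain, and measures
how the two acquisitions compare.

## What the pipeline computes

For each gene *g* and sample *s* (timepoint × replicate):

1. **Peptide ratios** — r₍p,s₎ = I_L / I_H per peptide, NA if either
   channel is missing (a zero MS intensity means non-detection).
2. **Singleton masking** — if a gene has exactly one non-NA peptide
   ratio in a sample, that lone value is set to NA.
3. **Protein ratio** — R₍g,s₎ = median over peptide ratios, kept only
   when backed by ≥ 2 distinct peptides.
4. **Detection filters** — stage 1 keeps genes quantified in ≥ 2 of 3
   replicates at any time point; stage 2 (the *processed dataset*)
   additionally requires ≥ 2 peptides and heavy-control detection in
   ≥ 2 of 3 replicates at **both** time points.
5. **Crosslink enrichment** — a protein is treated as genuinely
   RNA-bound if detected only in UV-crosslinked samples, or enriched
   there with BH FDR < 0.05 and linear FC > 1.5 (Welch t on
   mean-normalized log₂ intensities, 4 vs 4 samples).
6. **Differential RNA association** — per gene, a two-sided t-test of
   log₂ R between the 10 min and 1 h time points (Welch by default),
   BH-corrected; the primary call requires p < 0.05 **and**
   log₂FC = mean log₂R(1 h) − mean log₂R(10 min) beyond the dataset's
   own 10th/90th percentile thresholds (type-7 estimator).
7. **Acquisition metrics** — detected-protein counts, pairwise R² of
   log₂ raw intensities between replicates, per-protein MaxSD (the
   larger of the two time points' replicate SDs of L/H ratios),
   missingness, and the cross-acquisition R² of per-gene log₂FC.

Normalization options for peptide intensities: mean/median centering,
cyclic loess (MA-trend removal against a row-mean reference or
pairwise), a vsn-style variance-stabilizing glog calibration
h(x) = arsinh(a_s + b_s·x)/ln 2, or pass-through for DDA tables whose
ratios were already normalized upstream. Imputation options for the
protein ratio matrix: MIN×0.5 (limit-of-detection assumption) and
missForest-style iterative random-forest prediction (missing-at-random
assumption).

A first-class synthetic generator (`trapquant.synthetic`) draws
ground-truthed experiments in both file dialects — 2 time points × 3
replicates × H/L channels plus a 4-vs-4 crosslinked/non-crosslinked
arm, with intensity-dependent (MNAR) and random (MCAR) missingness —
so every stage is testable without any deposited raw data.

## Worked example

```bash
trapquant simulate --out demo --seed 11 --n-proteins 300
trapquant run-dia --input demo/dia_report.tsv --design demo/dia_design.tsv \
    --cl-intensities demo/cl_intensities.tsv --out demo/run_dia --seed 11
trapquant run-dda --input demo/peptides.txt --design demo/dda_design.tsv \
    --cl-intensities demo/cl_intensities.tsv --out demo/run_dda --seed 11
trapquant compare demo/run_dda demo/run_dia
```

The DIA run's `summary.json` reports (seed 11): 300 genes ingested, 172
passing the processed-dataset filters, 140 testable at both time
points, percentile thresholds p10/p90 = −0.160/+0.218 log₂ units, 13
significant by the primary rule (8 after BH), 120 crosslink-enriched,
and 6 significant *and* enriched — the headline "changed RBP" set. The
comparison report shows the expected acquisition contrast:

```json
"arm_a": {"acquisition": "DDA", "n_processed": 149, "median_max_sd": 0.160},
"arm_b": {"acquisition": "DIA", "n_processed": 172, "median_max_sd": 0.090},
"median_max_sd_shared": {"arm_a": 0.147, "arm_b": 0.090, "n_shared": 135},
"n_significant_both": 11, "n_sign_conflicts": 0,
"log2fc_r2": {"all_shared_tested": 0.77, "crosslink_enriched_both": 0.84,
              "significant_in_either": 0.98, "significant_in_both": 0.99}
```

DIA analyzes more proteins with lower inter-replicate ratio scatter;
fold-changes agree increasingly well as the gene set is restricted to
confidently measured proteins; no gene is significant in both arms
with opposite sign.

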