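# Methods

This note documents the models, rules and numerical choices behind
`trapquant`, and what its synthetic benchmarks do and do not show about
real data.

## Quantitation model

SILAC light/heavy ratios are treated as the primitive quantity: the
light channel carries the treated sample, the heavy channel the mock
control of the same run, so instrument- and run-level effects common to
both channels cancel in the ratio. Ratios are carried on linear scale
in tables; all statistics are computed on log₂ ratios (differences of
means of logs, not ratios of means — the alternative is available via
config for sensitivity checks).

The chain is: peptide ratio → singleton masking → per-gene median →
detection filters → tests. Order matters: masking runs before
aggregation so that a gene represented by one lone peptide value in a
sample contributes nothing there, and a protein quantity is only
reported when backed by ≥ 2 distinct peptides. "Peptide" means a
channel-stripped sequence ignoring charge; two charge states of one
precursor count once toward every two-peptide rule. This is the
conservative reading where precursor- and peptide-level counting could
diverge.

Gene-ambiguous features (a Genes field with several ";"-separated
symbols) are dropped with a logged count before aggregation; there is
no principled way to split their signal at gene level. Duplicate
(feature, sample) cells are an error rather than silently summed, since
the pivot to a matrix presumes feature identity is unique per run.

## Statistics

**Two-sample test.** Welch's unequal-variance t-test is the default;
with n = 3 per group the equal-variance assumption of the pooled test
is untestable, and Welch degrades gracefully when it fails. Note a
measurable property at this depth: under an exactly-null simulation
with equal variances, Welch's Satterthwaite approximation is
conservative (empirical rejection ≈ 0.033 at α = 0.05 on 2000 null
genes), whereas the pooled test (config `equal_var=True`) is exact and
rejects at the nominal 5%. The acceptance script reports the
exact-calibration route; both are exposed.

Degenerate inputs: both groups constant and equal → p = 1; constant
but different → the smallest positive double rather than 0; fewer than
two values in either group → missing p.

**Multiple testing.** BH step-up q-values are computed in-package
(q₍ᵢ₎ = min over j ≥ i of p₍ⱼ₎·m/j, capped at 1; missing p-values are
excluded from m and propagate as missing q). The implementation is
verified in tests against both a naive O(m²) min-over-suffix oracle and
statsmodels' `fdr_bh`.

**Percentile thresholds.** The 10th/90th percentiles of the tested
genes' log₂FC distribution serve as the fold-change gate, computed with
the inclusive linear-interpolation ("type 7") estimator. They are
computed after the insufficient-quantitation exclusion, over exactly
the genes tested — genes with < 2 ratios at either time point neither
receive a call nor shape the thresholds. Fewer than 10 testable genes:
thresholds are unavailable and only BH flags are produced.

**Crosslink enrichment.** The 4 crosslinked and 4 non-crosslinked
samples (2 light + 2 heavy per side) are treated as independent
observations; whether light/heavy pairs should be treated as paired is
not decidable from the data layout, and independence is the
conservative choice at this n. Exclusivity (detected in ≥ 1 CL, 0
non-CL samples) short-circuits the test.

The headline "significantly changed RBP" count intersects the primary
differential call with crosslink enrichment, so a protein must both
move between time points and be credibly RNA-bound.

## Normalization

All methods preserve the missingness pattern exactly and operate on the
full matrix; the Group 1–4 annotations (10 min light/heavy, 1 h
light/heavy) are reporting metadata, matching a single normalization
run over all four groups.

* **Scalar** (mean/median): each sample is shifted so its statistic
  equals the grand mean of per-sample statistics — exact to machine
  precision by construction.
* **Cyclic loess**: per iteration, each sample's M = xᵢ − ref is
  smoothed against A = (xᵢ + ref)/2 (lowess, span 0.7, 3 iterations,
  tolerance 1e-4) and the fit subtracted. The default `fast_reference`
  mode corrects against the row-mean reference; `pairwise` mode
  corrects every pair symmetrically. Pairs sharing < 10 features are an
  error. A monotone fitted correction preserves within-sample rank
  order.
* **vsn-style glog**: per-sample affine calibration inside an arsinh,
  h(x) = arsinh(a_s + b_s·x)/ln 2, fit by minimizing the profile
  negative log-likelihood (residuals against per-feature means, plus
  the −Σ log h′ Jacobian term that forbids the degenerate b → 0 fit)
  with L-BFGS-B, inside a least-trimmed-squares loop that refits after
  setting aside the 10% of features with the largest residual sum of
  squares. Both likelihood terms run over the same kept cells — an
  asymmetric variant (Jacobian over all cells) is exploitable by the
  optimizer and was rejected. This is an explicitly simplified
  reimplementation of the variance-stabilization idea, not a port of
  the reference ML machinery; it is validated behaviorally (the
  SD-vs-rank-mean trend on multiplicative+additive noise fixtures is
  flat, |slope| < 0.05). Output is marked `glog`: ≈ log₂ x plus a
  constant for large x.
* **none_passthrough**: for DDA tables whose light/heavy ratios were
  already normalized upstream at ratio level; that upstream scheme is
  deliberately not reimplemented.

## Imputation

Operates on the protein-level log₂ ratio matrix of genes with ≥ 2
quantitations at either time point (the stage-1 set).

* **MIN×0.5**: missing → 0.5 × column minimum on linear scale,
  identically column minimum − 1 on log₂ scale. One rule, implemented
  once; the two phrasings agree to float rounding (1 ulp) when
  evaluated through log₂.
* **Random forest**: missForest-style — initialize missing cells at
  column means, revisit columns in increasing-missingness order,
  regress each on the others (100 trees) and re-predict its missing
  cells; stop on stall (relative change of imputed values increases)
  or after 10 rounds. Deterministic given the mandatory seed; observed
  cells are never modified. After RF imputation, genes that had ≤ 1
  observed quantitation at a time point are flagged
  `prediction_not_robust` and excluded from significance calls — their
  imputations are extrapolations with essentially no support.

## Synthetic data

The generator emulates the study design: 2 treatment durations × 3
biological replicates, light = treated / heavy = mock in every run,
plus a 4-vs-4 crosslinked/non-crosslinked arm at protein level. On log₂
scale: heavy = baseline + peptide ionization offset + replicate effect
+ channel noise; light adds the true log₂ L/H ratio. The replicate
effect is shared by both channels of a run and cancels in the ratio —
ratio scatter comes from per-channel noise (sd `channel_sd_log2` per
channel). Detection is a logistic function of log₂ intensity (MNAR)
times (1 − MCAR rate), drawn independently per peptide × sample ×
channel; a correlated-channel option exists because SILAC pairs
co-elute.

Defaults (the package's standing description of the emulated
experiment): baseline log₂ ~ N(17, 2²); geometric peptide counts with
mean 4; 10% of proteins changed by ±1 log₂ unit at 1 h; replicate
effect sd 0.2; channel noise sd 0.15; 70% of proteins true RBPs with
8-fold crosslink enrichment, 30% silica background binders. The
acquisition contrast gives the DDA arm a 75% peptide subset, 1.5×
channel noise, and a sharp detection cutoff (midpoint 15.5, slope 3.0),
versus the DIA arm's deeper but blurrier detection (midpoint 14, slope
0.3) and extra charge states. That combination reproduces, at smaller
magnitude, the observed acquisition pattern: DIA detects more proteins
yet carries more missing cells among its detected set, with lower
replicate scatter of ratios.

What passing these benchmarks does **not** show: the generator has
homogeneous sample preparation (no batch or time-point-specific prep
effects), peptide counts independent of abundance, Gaussian noise, and
no interference or mis-identification — so absolute missingness
percentages and R² levels on real data will differ; only the
directional and calibration properties transfer.

Problem sizes in tests and the acceptance script (80–2000 proteins, 20
replicate simulations for the FDR check) were chosen so that each
assertion's effect size is resolvable against its own sampling noise;
e.g. a median-MaxSD direction is asserted at 300–400 proteins because
the medians' sampling error at ~100 genes exceeds the configured
separation.

## Pipeline and determinism

`run_pipeline` executes ingest → normalize → quantify → stats
(→ impute) → metrics and writes TSV tables plus `summary.json` with the
gene counts surviving each stage, thresholds, and a SHA-256 config
fingerprint (output location excluded) that every table carries in a
header comment. All randomness flows from explicit seeds; no output
artifact contains a timestamp, so identical config + inputs + seed give
byte-identical run directories. `compare_acquisitions` consumes two run
directories and reports per-arm counts, significant-set overlap and
sign conflicts, median MaxSD (globally and restricted to proteins
quantified in both arms — the restriction isolates acquisition
precision from detection-range composition), and cross-acquisition
log₂FC R² at four restriction levels.

The command-line interface (`trapquant simulate / run-dia / run-dda /
compare`) is a thin layer over these functions; exit codes distinguish
configuration (2), schema/data (3) and other (1) failures.

## Known limitations

* Gene-symbol resolution only; no protein-group parsimony inference.
* No retention-time, m/z or spectrum-level modelling in the simulator.
* The vsn-style calibration is a simplified reimplementation (see
  above) and is not expected to match reference implementations
  numerically, only behaviorally.
* Welch p-values at n = 3 are conservative; see Statistics.
* No quantile normalization, kNN/QRILC imputation, or moderated
  (empirical-Bayes) tests.
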