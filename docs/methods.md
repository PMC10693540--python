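# Methods

`toxsig` re-implements, as a tested pipeline, the statistical workflow used to
derive transcriptional signatures of mitochondrial electron-transport-chain
(ETC) inhibition from targeted RNA-seq (TempO-Seq-style) count data, together
with the respirometry normalization used to define mitotoxic exposure windows.
This note records the models, their assumptions, the defaults, and the design
choices made where the workflow left details open.

## Count model and differential expression

Counts are modelled genewise as negative binomial,
`K_gj ~ NB(mean = s_j q_gj, dispersion = alpha_g)` with a log-link GLM
`log q_gj = X_j beta_g`. The design is either pairwise (intercept + condition)
for one treatment against its vehicle control, or batch-aware
(intercept + experiment dummies + condition) for merged class-level datasets
spanning two experiments; the condition coefficient then estimates the
marginal class effect across batches.

* **Size factors** are median-of-ratios: per sample, the median (taken on the
  log scale) over genes of count / gene geometric mean, restricted to genes
  positive in every sample, rescaled to geometric mean 1. A `poscounts`
  pseudo-reference fallback exists for sparse matrices.
* **Dispersion** is method-of-moments on normalized counts,
  `alpha_hat = max(0, (s2 - mu)/mu^2)` with the within-replicate-group pooled
  variance, shrunk halfway (weight 0.5, configurable) toward a fitted trend
  `alpha_tr(mu) = a0 + a1/mu`, floored at 1e-8. This deliberately replaces
  empirical-Bayes shrinkage with a simpler, documented estimator; the
  consequence is that gene counts from a re-analysis of real data agree with a
  reference DESeq2 analysis approximately rather than exactly (the fold-change
  estimates themselves agree closely; see the cross-check test). The 0.5
  weight makes the 3-vs-3 Wald test hold its nominal level in the NB null
  calibration, between the anti-conservative raw estimate and the conservative
  pure trend.
* **Fitting** is IRLS, vectorised across genes (deviance tolerance 1e-8,
  max 100 iterations, non-converged genes flagged, all-zero genes excluded
  with NaN statistics). Wald p-values use the standard-normal reference;
  `log2FoldChange = beta_condition / ln 2`, `stat = log2FoldChange / lfcSE`.
* **Significance** follows the explicit rule set: baseMean > 10 (replacing
  automatic independent filtering), padj < 0.05 (Benjamini–Hochberg) and
  |log2FC| > 0.585 (1.5-fold), all strict.

Quality control drops samples with library size strictly below 200,000 reads
before any statistics. Probe panels from two experiment rounds are harmonized
on a shared reference response: probes identical in both panels are kept;
for a gene whose probes differ, the probes are kept iff the sample SD of the
gene's paired log2 fold changes (|Δ|/√2 for a pair) is below 0.1. The
reference condition is a parameter because the selection is defined relative
to one treatment response.

## Class analysis

Per compound, the reference concentration is the one with the most DEGs
strictly below the cytotoxicity threshold (ties toward the lower dose). The
class dataset merges each member compound at its reference concentration with
the vehicle groups of every contributing experiment, keeping the experiment
id for the batch-aware design. Per-class significant sets are decomposed into
the seven exact three-set Venn regions; "unique" means significant in exactly
one class. Fold-change concordance of the triple-intersection genes is the R²
of one pooled OLS over the three pairwise class comparisons, each pair entered
in both orientations so the value is invariant to class order; a per-pair mode
is provided because the pooling convention of the original correlation plot is
not uniquely determined.

The mitotoxic subset keeps (compound, concentration) pairs whose basal OCR is
at or below 60 % of vehicle control (a ≥ 40 % drop) while viability stays at
or above 75 % (the sub-IC25 window).

## Over-representation and upstream regulators

ORA uses the hypergeometric Z-score
`Z = (r - nR/N) / sqrt(n (R/N)(1-R/N)(1-(n-1)/(N-1)))` over the measured
universe N (genes passing the baseMean filter; parameterizable), selected
genes R, measured set members n and selected set members r; the numerator and
denominator are exactly the hypergeometric mean and finite-population SD, and
are verified against pmf enumeration. Significance combines |Z| > 2 with a
one-sided label-permutation p-value (default 1,000 permutations, add-one
correction; one shared permutation stream for all sets). Selection is
unsigned by default (a gene counts regardless of direction), with signed
variants available. The permutation scheme (labels, one-sided) is our choice;
the original tool's scheme is not documented at that level.

Upstream-regulator analysis operates on an explicit signed, weighted
regulator→target edge list (no proprietary knowledge base is reconstructed).
For each regulator, over targets that are differentially expressed,
`z = Σ w s_R s_D / sqrt(Σ w²)`; |z| ≥ 2 predicts activation (positive) or
inhibition (negative), gated on a BH-corrected right-tailed Fisher exact
overlap p < 0.05 across regulators. Regulators with no DE targets are flagged
`none` with undefined z.

## Dose–response modelling

The trend prefilter is a Williams-type test: treated group means are
amalgamated by weighted pool-adjacent-violators to be monotone, and the
highest amalgamated mean is compared with control, scaled by the pooled
within-group SE. Both directions are computed and the larger statistic kept;
the permutation null re-applies the same max-over-directions rule, so the
p-value remains calibrated despite the data-driven direction choice (verified
by null simulation). Genes pass at p < 0.05 and max fold change > 1.5. The
classical table-based p is dose-count dependent, hence the permutation p
(default 10,000 permutations in the API, fewer in the pipeline default).

Benchmark-dose curves use the four-parameter exponential model
`m(d) = a (c - (c-1) exp(-(b d)^g))`, fitted by trust-region least squares
with an analytic Jacobian in `(a, log b, c, log g)`, multi-started over a
log-spaced rate grid extended well below `1/d_max` so shallow curves are
reachable. The benchmark dose inverts the fitted curve in closed form at the
benchmark response, default a 10 % relative change from the modelled control
response (a control-SD option exists); targets outside the fitted range give
a flagged undefined BMD. Per-gene BMDs are summarised as accumulation curves
(cumulative count vs concentration).

A practical note on accuracy: with multiplicative noise of CV 10 %, a 10 %
relative benchmark response lies about one noise-SD above baseline, and the
sampling distribution of the least-squares BMD has a median relative error
near 30 % on a 3-decade, 7-point dose ladder — confirmed by starting the
optimiser at the generating parameters, i.e. this is an information limit of
the design, not an optimiser artifact. The error scales down with noise once
the ladder resolves the BMD (≈ 16 % at CV 5 % on a 2-decade ladder). BMDs
from single-curve fits at realistic noise should therefore be read as
order-of-magnitude potency estimates, which is how the accumulation plots use
them.

## Respirometry

Raw OCR is mapped to percent of control as
`100 (raw - mean(positive control)) / (mean(vehicle basal) - mean(positive
control))`: the positive control (a full ETC inhibitor) defines
non-mitochondrial respiration (0 %), the vehicle basal mean 100 %; optional
rescaling to the mean of ≥ 2 non-effective concentrations. LOELs come from
one-way ANOVA followed by Dunnett's many-to-one comparisons
(`scipy.stats.dunnett`); the LOEL is the lowest concentration with adjusted
p < 0.05.

## Synthetic data generator

The generator emulates the study design so that every stage is testable
without access to the original data: ~3,000 genes (1–2 probes each), two
batches, three compound classes with log-spaced µM concentration series and
3 replicates, vehicle groups per batch, NB counts with constant gene-level
dispersion (default 0.05, a free choice — the replicate variance of the real
system is not published), log-normal library sizes (mean 2e6, CV 0.3, with a
configurable number of low-depth samples under 200,000 to exercise QC), and a
gene-wise log-normal(0, 0.1) batch factor small enough for the batch-aware
design to absorb. A fraction of genes (default 10 % common to all classes +
2 % unique per class; each responsive gene in exactly one category) follows an
Exp5-shaped fold-change curve with peak effect 1.5 log2 units, midpoint
log-uniform inside the tested range, shape exponent in [0.8, 2]. Matching
artifacts are generated alongside: a signature gene set plus size-matched
random decoys, signed regulator networks with a configurable consistent-edge
fraction, and OCR/viability endpoint tables in which classes CI and CIII are
mitotoxic (Hill-shaped OCR decline) and cytotoxicity sets in an order of
magnitude higher.

What the generator does *not* emulate: probe-level sequence biases, sample
swaps, outlier replicates, correlated gene modules, or dispersion–mean
relationships beyond the fitted trend. Passing tests therefore demonstrate
the correctness and calibration of the statistics under the stated model, not
robustness to every artifact of real TempO-Seq data.

## Numerical and degenerate-input conventions

Strict inequalities everywhere the rule set states them ("below 200,000",
"padj < 0.05", "|log2FC| > 0.585", "baseMean > 10"). Ties in reference-
concentration selection break toward the lower dose. A gene set spanning the
entire measured universe has an undefined Z (degenerate variance) and is
skipped with a warning. Permutation p-values use the add-one correction and
never return 0. IRLS clamps linear predictors to ±30 to avoid overflow;
Exp5 clips `log b` to ±50 and `log g` to ±3 (shape exponents outside
[0.05, 20] are not identifiable at 7 doses). The Dunnett critical values come
from scipy's multivariate-t implementation.

## Pipeline

Stages (`simulate → qc → de → class → ora → upstream → bmd → ocr`) read and
write plain TSV in the output directory and can be re-run individually from
the CLI; a JSON manifest records the seed, thresholds, package version, stage
list and warning counts, which — together with the config file — suffices to
reproduce every output. All randomness flows from a single configured seed
(per-purpose child seeds are derived by fixed offsets), so reruns are
byte-identical.

Default problem sizes in the bundled examples and the acceptance script
(hundreds of genes, two compounds per class, five-concentration series) are
chosen so a full run completes in minutes on one core while leaving every
statistical property measurable; all sizes scale through `SimConfig`.
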