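# Methods

## Carrier-burden model

The unit of observation is the kindred. Let a cohort contain `n` kindreds,
`k` of which carry at least one qualifying allele of the gene under study; a
kindred counts once however many qualifying variants, affected members or
alleles it has. Under the null hypothesis, carriers arise independently at
the background probability `p0` estimated from a population reference, and

    p = P(X >= k),  X ~ Binomial(n, p0)

is the exact one-sided tail, computed by summing `binom.logpmf` terms with
log-sum-exp (numerically safe down to tails far below double-precision
underflow of individual factors). Fold enrichment is `(k/n)/p0`. The test is
conservative by discreteness — the realized type-I error at α = 0.05 is
below nominal, which the calibration check in the acceptance script
confirms by simulation.

The qualifying filter keeps a variant iff

1. reference allele frequency `AC/AN` **strictly** below `max_maf`
   (default 10⁻⁵); a variant absent from the reference is encoded as
   `AC = 0` over a valid `AN`, i.e. frequency 0 — never as a missing value;
2. consequence in the protein-altering set {missense, inframe_indel,
   frameshift, stop_gain};
3. when damage scores are supplied, combined score ≥ 0.7 (inclusive).
   A missing score for a filtered variant raises; silent passes would bias
   the burden upward.

No folded minor-allele logic is applied: qualifying variants are ultra-rare
alternates, for which the alternate-allele frequency *is* the MAF.

The background carrier probability aggregates per-variant Hardy–Weinberg
carrier probabilities `c = 2p(1−p) + p²` through the product form
`p0 = 1 − Π(1 − cᵢ)` (via `log1p`), which stays valid when many variants
qualify and reduces to `Σ2pᵢ` in the rare limit. Whether a published
background percentage was computed from carriers or summed allele
frequencies is often unstated; the package therefore also accepts `p0`
directly as configuration. For backgrounds estimated from small references,
`fisher_burden_test` provides the conditional alternative.

One discrepancy worth documenting: the cohort fixture's carrier fraction is
5/63 = 7.9%, and that is what the package reports; a "~6% (5/63)" figure
sometimes quoted for the same ratio is arithmetically inconsistent and is
not reproduced here.

## Combined VEP damage score

Raw predictor outputs are incomparable across tools, so each is reduced to
a percentile against the gene-specific background of reference missense
variants: the fraction predicted less damaging, with exact ties counted ½
(mid-rank). Mid-rank is chosen over strict-less because it is the standard
unbiased rank convention — a background member scores 0.5 in expectation
against its own distribution — and because the original tie rule is not
recoverable from published descriptions; the difference only matters for
discrete-valued predictors. Orientation (whether larger raw means more
damaging) ships as editable YAML (`lupuskit/data/predictors.yaml`); the two
log-likelihood-style predictors (ESM-1v, DeepSequence) are oriented
lower-is-damaging, the five bounded classifiers higher-is-damaging.

The combined score is the unweighted mean over predictors that have both a
raw score and a background; missing predictors are skipped and reported via
`n_used` rather than imputed. Classification as damaging uses score ≥ 0.7,
inclusive (a published worked example sits exactly at 0.70). The specific
published per-variant scores used in the cohort fixture are carried as
fixture data: reproducing them would require the external reference score
sets, which this package deliberately does not ship or download.

## Interferon-signature scores

**qPCR (6 ISGs).** Technical replicates are averaged on the Ct scale;
relative expression is `2^(−ΔCt)` with
`ΔCt = Ct_gene − mean(Ct_HPRT1, Ct_18S)`. The arithmetic mean of
housekeeping Cts (= geometric mean of expression) is the standard ΔΔCt
convention; the choice cancels in the control-median fold anyway for
samples measured on the same panel. Per-gene folds are taken over the
median of the healthy-control cohort, and the score is the median of the
six folds (even-length medians: mean of the two central order statistics).
Positivity is `score > 2.46`, strict — the published cutoff is defined as
an exceedance. The median construction tolerates gross corruption of up to
two of the six genes.

**NanoString (24 probes).** The calibrator arithmetic of commercial
software is not published in closed form; the package implements one
defensible, documented reading of "normalized to positive/negative
calibrators and reference probes", in three ordered steps:

1. lane scale: multiply each sample by
   (grand geometric mean of positive-calibrator counts)/(sample geometric
   mean); removes per-sample scale distortions exactly;
2. background: subtract the sample mean of negative-calibrator counts,
   floor at 1 (avoids zeros entering later geometric means);
3. content scale: multiply by (grand geometric mean of the three reference
   probes)/(sample geometric mean).

Scoring then mirrors qPCR with 24 probes, and the positivity threshold is
recomputed from the control cohort as mean + 2·SD of control scores with
the sample (n−1) SD. Published values of that threshold (2.75, elsewhere
2.758) are control-cohort-specific; they ship as constants in
`data/panels.yaml` for reference but are never asserted against recomputed
thresholds from other cohorts.

## Reporter-assay chain and statistics

Per well, `RLU = Firefly/Renilla` (Renilla must be positive; Firefly
non-negative). Duplicate wells are averaged at the RLU stage, then
`fold_stimulated = mean stimulated RLU / mean unstimulated RLU` per
construct × experiment, then `relative_fold = fold / WT fold` within each
experiment, making the wild type exactly 1 per experiment and rendering the
chain invariant to per-experiment rescaling of either luminescence channel.
The default observational unit for statistics is the per-experiment
relative fold (matching mean ± SEM over n experiments as reported in such
assays); well-level analysis remains possible by passing well-level groups.

One-way ANOVA is the textbook between/within sums-of-squares F. Dunnett's
many-to-one adjustment is computed by Monte Carlo: with pooled variance s²
on N − g degrees of freedom, the joint null of the comparison family
(correlated through the shared control) is sampled as independent group
means plus a shared chi-square variance draw, and the adjusted p of
comparison i is the add-one estimate of P(max_j |t*_j| ≥ |t_i|). Monte
Carlo was chosen over multivariate-t quadrature because it is transparent,
seed-reproducible and directly testable against a brute-force resampling
oracle; n_mc is configurable (default 10⁵ gives ≈3-decimal accuracy, and
the estimate is clamped below by the unadjusted t p-value so the
adjusted ≥ unadjusted invariant holds at any n_mc). Šidák adjustment
`1 − (1 − p)^m` is provided for the independent-family corrections used
alongside; routine omnibus alternatives (two-way ANOVA, rank tests,
mixed-effects fits) are outside scope and available in scipy/statsmodels.

## ΔΔG summaries

Quartiles use linear interpolation of order statistics (the common plotting
default; with n = 5 the quartiles land on interpolated positions 2 and 4).
Whiskers extend to the most extreme data points within quartile ± 1.5·IQR.
The stabilizing/destabilizing call (median below −0.5 / above +0.5
kcal/mol, else neutral) is a package convention with the tolerance set at
the typical noise floor of empirical force-field predictions; the
underlying direction is all the upstream science asserts.

## Synthetic-data generators

All generators derive independent substreams from one global seed via
`SeedSequence([seed, stream_id])`, so adding a generator never perturbs
another and fixed seeds reproduce tables byte for byte. Ground truth is
emitted in a sidecar (YAML via the CLI), never inferred from the data.

What they emulate, and defaults:

- **Cohort** (63 kindreds, carrier probability 5/63): each kindred
  independently carries one private qualifying missense variant (absent
  from the reference; ~20% homozygous); noise variants alternate between
  common missense (AF in 10⁻⁴–10⁻², failing the MAF criterion) and
  ultra-rare synonymous (failing the consequence criterion), carried at
  Hardy–Weinberg rates.
- **qPCR** (7 patients, 29 controls, injected fold 10, Ct noise SD 0.2):
  patient ISG expression is the control baseline times the injected fold,
  i.e. Ct drops by log2(fold); housekeeping genes are unshifted; noise is
  Gaussian on the Ct scale. The injected fold of 10 sits mid-range of
  typical positive patient scores (≈4–26).
- **NanoString** (27 controls): per-sample log-normal lane distortions
  multiply every probe including the positive calibrators, and an additive
  per-sample background contaminates every probe, so each normalization
  step does real work; count noise is log-normal.
- **Reporter plates** (4 experiments, duplicate wells, cv 0.1, WT fold 10):
  within an experiment all constructs share an unstimulated baseline RLU;
  construct c's planted stimulated RLU is baseline × WT-fold ×
  multiplier[c], so its expected relative fold is the multiplier; Firefly
  carries mean-one log-normal noise at the stated CV. Log-normal noise is
  the natural shape for luminescence (positive, multiplicative).
- **ΔΔG**: Gaussian per-model draws around planted per-(variant, complex)
  means, five models by default.

What they do **not** emulate — and hence what passing recovery tests does
not show about real data: linkage and population structure, batch and
plate-position effects, probe cross-hybridization and saturation,
transfection-efficiency drift between constructs, or heavy-tailed assay
failures. The simulators validate the arithmetic and its invariances, not
assay robustness.

## Problem sizes and numerics

Tests and the acceptance script use deliberately modest sizes chosen to
make the statistical assertions sharp but cheap: 100 simulated patients for
qPCR fold recovery, 2,000 null cohorts for burden calibration, background
N = 10⁴ for the percentile-oracle check, 10⁶ Monte-Carlo draws for the
Dunnett-vs-oracle comparison, 50 experiments for reporter recovery. The
exact binomial tail agrees with literal float summation to 10⁻¹⁰ relative
error over all n ≤ 200. Degenerate inputs fail loudly: zero allele number,
empty backgrounds, missing housekeeping Cts, non-positive calibrators or
Renilla readings, absent wild type, and duplicate (variant, complex, model)
triples are all errors, not silent defaults; the one warning-not-error case
is an empty qualifying reference set, which yields background frequency 0
with a warning since that is a legitimate (if degenerate) analysis state.
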