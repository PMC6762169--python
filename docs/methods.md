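# Methods

`lvsig` re-implements, as a tested and reusable pipeline, a
differential-expression analysis for predicting lymphovascular space
invasion (LVSI) in endometrial cancer from two-channel DNA-microarray
data: a gene signature is selected by three successive filters, samples
are hierarchically clustered on that signature, the two-group dendrogram
cut is scored as a binary diagnostic test against pathological LVSI
status, and the clinicopathological covariates are tested for
association with LVSI.

## Data model

Expression values are log2 ratios of Cy5 (sample) to Cy3 (common
reference) fluorescence, one value per gene and sample.  A probe whose
fluorescence falls below the scanner's detection limit carries no
trustworthy ratio; these cells are tracked in a parallel boolean mask and
treated as missing everywhere: every mean, variance, median and test is
complete-case per gene.  No imputation is applied during selection; the
study's source describes no imputation rule, and the detection filter
(below) caps the per-class missing fraction so complete-case statistics
remain well powered.

Per-array normalization is reduced to a documented contract: per-sample
median centering of detected log ratios.  The original analysis delegated
normalization to scanner software without describing it, so the minimal
idempotent operation replaces it.  Synthetic data are generated centered,
so pipeline results do not hinge on this choice.

## Signature selection

For classes of size n+ (LVSI-positive) and n− (negative), a gene is
selected when it passes all three filters, applied in order:

1. **Detection filter.** Excluded iff its below-detection fraction
   exceeds 0.25 (strict) in the positive class or in the negative class.
   At the reference class sizes 26/62 this is exactly the rule "missing
   in ≥7 of 26 positives or ≥16 of 62 negatives"; the fractional form
   generalizes the rule to other sample sizes.
2. **Mean-difference filter.** mean+(g) − mean−(g) ≥ 1 log2 unit
   (inclusive), computed over detected values.  The rule is signed —
   only genes up-shifted in the positive class qualify — matching the
   original selection; `signed=False` switches to |Δ|.
3. **Student's t-test.** Pooled-variance two-sample t on detected
   values, two-sided p from the t distribution with n1+n2−2 df; selected
   when p < 0.005 (strict).  "Student's t-test" is read as the
   equal-variance test, which is what the name denotes; Welch is
   available via `equal_var=False`.  No multiple-testing correction is
   applied: the fixed p < 0.005 rule *is* the procedure.

Degenerate cases: a gene with fewer than two detected values in a class
is untestable (never selected); zero within-class variance gives |t| = ∞
(p = 0, selected if the other filters pass) for unequal means and t = 0
(p = 1) for equal means.  The selected list is ordered by ascending
p-value, ties broken lexicographically by gene id, for determinism.

## Cluster classifier

Samples are agglomeratively clustered on their signature-gene vectors
under Euclidean distance and the dendrogram is cut at the root (the last
merge) into exactly two groups — the simplest reading of "divided into
two groups".  The linkage used by the original (proprietary) software is
unknown; the default here is **average (UPGMA)**, the historical default
of microarray clustering tools, with `complete` and `ward` selectable
and all three covered by an exhaustive-agglomeration oracle in the test
suite.  Genes are not rescaled before clustering (log ratios share a
scale already).  Residual below-detection cells among signature genes
are imputed with the gene's across-sample mean of detected values, since
Euclidean distance needs complete vectors; the detection filter keeps
this imputation mild (≲25 % of a class).

The cluster with the higher proportion of LVSI-positive samples is group
**A** and is the test-positive call; ties are broken by the higher
absolute positive count, then by containing the first sample in input
order.  Group B is the test-negative call.

## Diagnostic evaluation

The A/B call against pathological truth gives TP/FP/FN/TN and
sensitivity, specificity, PPV, NPV and accuracy as exact fractions.  A
metric with a zero denominator is reported as *undefined*, never as 0.
Reports format proportions as percentages with one decimal.

## Clinicopathological statistics

Covariate-by-LVSI 2×2 tables (stage I/II vs III/IV, histology, grade 1
vs 2/3, myometrial invasion, lymph-node metastasis among the evaluated,
recurrence) use the two-sided Fisher exact test with the "probability ≤
observed" two-sided rule — the convention of mainstream statistical
software.  Age and BMI use the Mann-Whitney U test: exact null
distribution when both samples are ≤20 without ties, normal
approximation with continuity and tie correction otherwise (the regime
of the 26/62 cohort).  Overall survival uses the Kaplan-Meier
product-limit estimator per LVSI group and the two-sided log-rank test;
with no events in either group the log-rank p is flagged undefined.
Significance is declared at p < 0.05.

## Synthetic data generator

The study's raw 88-sample microarray data are not publicly deposited, so
a generator provides datasets with the statistical structure the
analysis assumes.  Defaults are the study conditions: 26 positive and 62
negative samples, 1000 genes of which 55 are planted, effect size 1.5
log2 units, per-gene noise SD 0.5, below-detection rate 0.05.

* Log ratios are Gaussian on the log2 scale — background genes have
  class-independent mean 0; planted genes are shifted **upward** in the
  positive class by the effect size, matching the signed selection rule.
  The Gaussian choice is an assumption (no distributional model is
  stated for the real arrays); noise SD 0.5 is a typical per-gene spread
  for centered two-channel log ratios, and effect size 1.5 keeps planted
  genes comfortably above the 1-log2 selection threshold while leaving
  the test non-trivial at 5 % dropout.
* Below-detection cells are generated then masked, independently of the
  values (missing at random), so tests can vary dropout and signal
  independently.  Real below-detection is intensity-dependent
  (missing-not-at-random); the generator does not emulate that, so
  passing tests show correctness of the complete-case machinery, not
  robustness to informative missingness.  Dye bias, spatial artifacts
  and probe-level effects are likewise out of scope.
* Clinical covariates are allocated conditional on LVSI status to match
  the study cohort's per-covariate 2×2 margins exactly in deterministic
  mode (or permuted within class in stochastic mode).  The cohort table
  groups stage I/II, III/IV and grade 2/3; the within-group splits used
  here (e.g. stage I vs II) are assumptions that collapse back to the
  printed counts under the standard dichotomies.  Recurrence margins
  (8/26 vs 4/62) are an assumption: the cohort table prints none.  The
  printed myometrial-invasion rows (<50 %: 20 positive vs 10 negative)
  are reproduced exactly as given, although they sit oddly with the
  prose claim that LVSI accompanies deep invasion; the package reports
  the table it is given and does not resolve this.  Covariates are drawn
  independently of each other and of the expression values — real
  covariates are correlated (e.g. stage with nodal status), so
  associations between covariates are not emulated.
* Age and BMI are Gaussian per class with the cohort's means and SDs,
  clipped below at 15 to avoid impossible values.
* Survival is exponential with baseline hazard 0.004 per month for
  LVSI-negatives (≈79 % five-year survival, consistent with early-stage
  endometrial cancer), hazard ratio 3 for positives, and administrative
  censoring at 120 months — the simplest model supporting log-rank power
  checks.

Identical configuration and seed give bit-identical datasets.

## Numerical and design choices

* Matrix I/O writes full-`repr` precision so write∘read is the identity.
* Parse errors carry file and line number and name the offending id or
  cell.
* Median centering is idempotent up to floating-point rounding of the
  interpolated even-count median (~1e-16 per pass).
* The t statistic and p agree with a textbook per-gene computation to
  1e-10 relative; the implementation is vectorized over genes with the
  detection mask applied.
* Fisher exact agreement with an exact-integer enumeration oracle is
  verified exhaustively on all 46 375 tables with total ≤ 30.
* Type-I error of the selection t-test is checked on 100 000 null genes
  at the study's class sizes (nominal 0.005 within 3 binomial SDs);
  planted-gene recovery is averaged over 20 seeds at the default
  conditions.  These problem sizes make the checks statistically sharp
  while keeping the default suite fast.
* End-to-end runs are deterministic under a fixed seed; every output
  file carries the seed and a 12-hex-digit SHA-256 hash of the run
  configuration.

## Known limitations

The generator's Gaussian, missing-at-random, covariate-independent
structure is idealized; agreement of the pipeline with its planted truth
bounds implementation correctness, not real-data performance.  The
identity of the study's actual 55 genes cannot be reproduced (raw data
undeposited), and the original linkage method is unknown, so the
two-group cut of real data could differ by linkage.  Confidence
intervals for the diagnostic metrics and ROC analysis are out of scope —
the cluster cut yields no continuous score.
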