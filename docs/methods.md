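# Methods

## Absolute-risk projection

Both risk engines share one discrete-time competing-risk recursion
(`bcrisk.projection`). Years are the projection unit; within a year the
disease hazard λ and the competing (non-breast-cancer) mortality hazard m
are constant, taken from the age band containing the year's starting age.
The probability of a disease event in year t is
`λ/(λ+m) · (1 − e^{−(λ+m)})` times the probability of reaching year t free
of both events, and the horizon risk is the sum over years. With m = 0 and
constant λ this collapses to `1 − e^{−λT}`, which the tests verify to
1e−12; adding mortality strictly lowers the risk.

Degenerate inputs: λ = m = 0 in a year contributes 0 (the 0/0 ratio is
defined as 0); a horizon of zero or an age span leaving the rates table is
an error rather than an extrapolation.

## Clinical (Gail) engine

The relative risk multiplies per-category terms for age at menarche, age at
first live birth, first-degree relatives, and biopsies, with two
interactions (biopsies × age ≥ 50, applied only in the 50-plus segment, and
first birth × relatives) and an atypical-hyperplasia multiplier that applies
only to women with at least one biopsy. UNKNOWN answers carry the neutral
(zero) term. The age-segment switch happens in the year containing the 50th
birthday.

The baseline hazard deflates the composite incidence by (1 − AR) so that it
refers to women with all factors at baseline; a cohort of baseline profiles
then averages exactly to the deflated population risk (tested). The numeric
bundle (`data/gail_coefficients.yaml`) is data-driven and swappable: the
log-RR terms transcribe the classic published values, while the (1 − AR)
fractions and the companion age-band rates table
(`data/rates_illustrative.tsv`) are illustrative, since no officially
calibrated Indonesian set is published with the workflow. The default
ethnicity group is the Asian-type bundle entry; unknown ethnicity labels
fall back to it.

## Polygenic engine

* **Merge rule.** Array calls always win; an imputed call substitutes only
  when the array genotype is missing and its INFO score strictly exceeds
  0.8 (the boundary case 0.8 is rejected, tested).
* **Raw score.** Weighted *sum* of effect-allele dosages. Sum rather than
  per-allele average is deliberate: standardization removes scale, and sums
  are the convention for published weight panels. A missing site contributes
  its reference expected dosage 2f, and the count of frequency-imputed sites
  is reported alongside the score.
* **Standardization.** Z = (raw − µ_ref)/σ_ref against a configurable
  reference distribution. When none is supplied, the Hardy–Weinberg
  expectation of the panel (µ = Σ 2wf, σ² = Σ 2w²f(1−f)) stands in.
* **Ancestry adjustment.** OLS of reference Z-scores on the first four
  principal components (statsmodels); a subject's adjusted score is the
  residual `z − (a + Σ b_k pc_k)`. PCs are consumed as input — computing
  them is outside this package's scope.
* **Absolute conversion.** `λ(t) = incidence(t) · exp(βz − β²/2)` with
  β = ln(1.61) per SD by default (the published per-SD odds ratio for this
  panel class; configurable). The `e^{−β²/2}` deflation pins the
  population-average hazard to the raw incidence when adjusted scores are
  standard normal; a Monte-Carlo test confirms the population calibration,
  and the algebraic identity at z = β/2 (hazard = incidence exactly) is
  checked to 1e−12. An empirical-distribution calibration would be an
  alternative; the log-normal form was fixed because it is closed-form,
  parameter-free beyond β, and exactly self-consistent under the generator's
  assumptions.

## Monogenic filter

All five criteria must hold: significance ∈ {pathogenic, likely
pathogenic}; review stars ≥ 2; no conflicting interpretation; dosage ≥ 1;
genotype quality ≥ 3. Both numeric thresholds are inclusive, matching their
"≥" statement; homozygous carriers count the same as heterozygous. Calls
with a missing dosage or GQ are unevaluable: excluded from carrier
determination but tallied and reported rather than silently dropped. The
filter is idempotent and monotone (tested), and star ratings arrive as
precomputed integers in the annotation table.

## Combined category

Absolute risks travel in percent end-to-end so the 1.7 threshold keeps its
printed units. The comparison is inclusive (≥ 1.7 % is elevated) — the
conventional boundary for this threshold; the source workflow does not state
the boundary convention, so the choice is documented here and configurable.
The max rule and the elevated-count stratification are both computed; their
consistency (count ≥ 1 ⇔ max elevated) is enforced at construction and
tested exhaustively.

## Evaluation statistics

* `roc_auc`: empirical ROC (ties count half), AUC = Mann–Whitney
  concordance; tested against a brute-force pairwise oracle at 1e−12. The
  95 % CI uses the DeLong structural-components variance.
* `combined_risk_auc`: the categorical combined classifier swept over a
  joint threshold applied to both scores (they share the 5-year-% scale),
  candidate thresholds being midpoints of the pooled distinct values plus
  ±∞ sentinels, with carriers elevated at every threshold; points are
  anchored at (0,0) and (1,1) and integrated by trapezoid. Applying
  per-score thresholds independently would be the alternative convention.
  With identical score vectors and no carriers it reproduces `roc_auc`
  exactly (tested), and it matches an exhaustive value-sweep oracle.
* t tests default to pooled variance with a Welch option.
* `adjusted_association` is a statsmodels logistic fit; constant covariates
  are dropped with a warning, perfect separation raises.
* `odds_ratio` reports the Wald cross-product estimate with a log-scale CI
  (0.5 continuity correction on zero cells, flagged) plus a conditional-MLE
  secondary estimate; median-unbiased-style estimators give slightly smaller
  values than the cross-product on the same table, which is worth knowing
  when comparing published figures.
* `ppv_npv` returns percent with two decimals. On the reconstructed
  study-style table (20, 129, 5, 151) the NPV is 53.93 % by arithmetic.

## Power analysis

Cohen's d uses the pooled SD. The sample-size formula is the two-sided
normal approximation `n = ⌈2(z_{α/2}+z_β)²/d²⌉`, rounded **up**; at
d = 0.396, α = 0.05, power 0.8 it yields 101 per group. The exact power of
the pooled t test at that design is 0.7997 by the non-central-t (the normal
approximation overstates power slightly); the Monte-Carlo estimator agrees
with the non-central-t oracle within simulation error and reproduces 0.80
at two decimals. Monte-Carlo power runs in vectorized chunks; 100,000
replicates take a few seconds.

## Genotyping concordance

Genotype tables are site × sample matrices of allele counts with −1 for a
no-call (query) or unknown truth. "Correct" means exact genotype match — a
het called hom-alt is wrong, consistent with the cell taxonomy separating
TP-het from TP-hom-alt. Cell codes: TP_HOM_ALT, TP_HET, TN, FP, FN
(a truth-variant site either missed or called with the wrong genotype),
NC, NA. Because a wrong-genotype variant call is a single FN cell, the
precision denominator (variant calls made) is counted directly rather than
from cells; the cell-consistency test therefore plants FP/FN/no-call errors
only. Metric denominators exclude NC/NA cells; callability tracks no-calls
separately. The per-site rule classifies a site concordant iff correct in
strictly more than 95 % of evaluable samples, with zero-evaluable sites
flagged NA.

## Synthetic cohort generator

Defaults are the study conditions: 149 cases / 156 controls; clinical
5-year scores 0.76 ± 0.44 (cases) vs 0.54 ± 0.31 (controls); adjusted PRS
0.41 ± 0.96 vs 0.02 ± 0.89; genetic 5-year scores 0.85 ± 0.41 vs
0.62 ± 0.33 (the 0.41 SD is used where two readings exist in the source
summaries); ages 47.86 ± 8.20 vs 44.26 ± 7.88; 14 carriers, all cases;
Chinese-ancestry fractions 73/149 and 41/156.

Clinical and genetic scores are drawn from a normal truncated at zero whose
pre-truncation parameters are solved numerically so the *truncated*
mean/SD equal the targets (only mean/SD are published; truncation preserves
the positivity of absolute risks). Adjusted PRS and ages are plain normal
(ages clipped to [25, 74.5] so profiles stay inside the eligibility window
and the rates span). Carriers are planted independently of the scores —
the source data show little factor co-occurrence — and ethnicity is a
binary Chinese/Indonesian label with the published marginals.

The genotype mode draws panel dosages under Hardy–Weinberg at the panel
frequencies, assigns case status by a logistic model on the standardized
PRS (slope β per SD), subsamples to the spec sizes from an oversized pool,
and draws null standard-normal PCs (an optional case-shift on PC1 creates
structure). It deliberately does **not** simulate linkage disequilibrium
between panel variants, imputation INFO-score error structure (beyond the
tag plumbing), score correlations between the clinical and genetic
components, or age–score dependence; passing tests therefore demonstrate
correctness of the pipeline arithmetic and its statistical behaviour under
these idealized conditions, not performance on real genotype data.

The truth/query pair generator plants `round(rate · n_eligible)` errors of
each kind (false positive, false negative, genotype swap, no-call) on
disjoint cells and returns the exact ledger, so concordance metrics can be
verified against hand counts.

## Problem sizes used in the checks

Monte-Carlo checks run at sizes chosen to keep the whole suite in seconds
while leaving 3-SE margins meaningful: 100,000 replicates for power and
population calibration, n = 5000 for logistic parameter recovery, 100
seeded replicates of the 305-subject cohort for the discrimination sanity
band (mean clinical AUC across replicates within [0.60, 0.74]; individual
replicates scatter with SE ≈ 0.03, so the band is a property of the
ensemble, not of each draw).

## Known limitations

* The coefficient bundle's (1 − AR) fractions and the rates table are
  illustrative; absolute-risk magnitudes shift with the calibrated tables a
  deployment would supply.
* The synthetic panel's weights/frequencies are a stand-in; results on it
  validate machinery, not any specific published panel.
* PCA projection, imputation, and annotation are consumed as inputs, never
  recomputed.
* The per-sample VCF reader assumes pre-split biallelic records and
  diploid genotypes.
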