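# Methods

## The problem and the estimands

Insulin resistance (IR) and impaired early-phase insulin secretion both
reshape the fasting metabolome, but observational associations confound
cause and consequence. The package implements two complementary analyses.

The **observational scan** regresses an SD-standardized physiologic
outcome on each standardized metabolite in turn (ordinary least squares
with covariates), reporting the metabolite coefficient with a two-sided p
from the t distribution at the residual degrees of freedom, and
Benjamini–Hochberg q-values over the scan. Outcomes are clamp M/I
(glucose disposal per unit plasma insulin during a hyperinsulinemic-
euglycemic clamp; strictly positive, in mg·kg⁻¹·min⁻¹ per mU/l × 100),
IGI30 = Δinsulin/Δglucose over 0–30 min of an OGTT, and the disposition
index DI = clamp M/I × IGI30. IGI30 and DI are log-transformed to
normality before standardization; samples with zero glucose change or
non-positive IGI30/DI are excluded with logged reasons — noisy OGTT data
genuinely produce such values and there is no defensible way to log them.
An optional sign flip reports associations in the direction of worsening
physiology (clamp M/I and DI fall as IR worsens).

**Mendelian randomization** treats an additive unweighted genetic risk
score as an instrumental variable for the exposure. The causal effect on
a metabolite is the Wald ratio β_IV = β_IV→M / β_IV→X with the
first-order delta standard error
SE_IV = |β_IV|·√[(SE_M/β_M)² + (SE_X/β_X)²]. This SE treats the two legs
as independent, which is exact in the two-sample design (instrument-
exposure effects from an external GWAS). In a one-sample design the legs'
sampling errors are correlated and the interval over-covers (we measure
≈0.975 instead of 0.95 in simulation); the calibration studies therefore
use the two-sample layout, which is also how such analyses are actually
run. Inference everywhere uses the normal approximation with
z₀.₉₇₅ = 1.959964 — appropriate at cohort sizes in the thousands — except
the scan and MR-Egger, which use t inference at their exact residual df.

Degenerate ratios: a zero instrument-exposure coefficient is a
weak-instrument error; a zero instrument-metabolite coefficient yields
β_IV = 0 with the analytic limit SE |SE_M/β_X| and a flag, since the
ratio itself is well-behaved there even though the relative-error formula
is not.

## Genetic risk scores

A score definition lists, per SNP: risk and other allele, a reference
risk-allele frequency (RAF), an optional proxy (linkage disequilibrium
r² > 0.8 required), and its availability route. Construction rules:

* **Harmonization.** Dosages are oriented to count the risk allele
  (d → 2 − d when the file counts the other allele); incompatible allele
  sets raise an error naming the SNP. Palindromic (A/T, C/G) SNPs cannot
  be oriented by allele labels alone; they are resolved by comparing the
  file's allele frequency with the declared RAF, and excluded with a
  report when either frequency is within 0.08 of 0.5 (strand
  indistinguishable). The window is configurable.
* **Absent SNPs** contribute the constant 2·RAF to every individual
  (reference-panel frequency imputation). Being constants, they do not
  count toward missingness.
* **One missing genotyped value** is replaced by that SNP's sample-mean
  dosage, computed post-harmonization over the analysis cohort's
  non-missing entries (the natural choice; other means would be equally
  defensible, so this is documented rather than assumed obvious).
* **More than one missing value** excludes the individual.
* Call rates at or below 95% trigger a warning naming the SNP.

## Summary-data estimators

Given per-SNP exposure (bx, sx) and outcome (by, sy) associations for
independent instruments:

* **Per-SNP ratios**: θ̂_j = by_j/bx_j, first-order SE sy_j/|bx_j|.
* **IVW**: θ̂ = Σ bx·by/sy² / Σ bx²/sy², SE = (Σ bx²/sy²)^−½ — an exact
  algebraic identity with inverse-variance pooling of the per-SNP ratios
  (tested to 1e-12). The fixed-effect SE is the default; a multiplicative
  residual scale floored at 1 is available for heterogeneous sets.
* **MR-Egger**: weighted least squares of by on bx with a free intercept,
  weights 1/sy², all pairs re-oriented so bx > 0. The slope estimates the
  causal effect and the intercept the average directional pleiotropy
  (consistent under InSIDE: instrument strength independent of direct
  effects). p-values use t at J−2 df. The default residual scale is the
  plain WLS estimate, under which the intercept test is exactly
  t-distributed (measured type-I error 0.050 at α = 0.05 over 3,000 null
  replicates); flooring the scale at 1, offered as an option, makes the
  test conservative (measured 0.015) and is only preferable when
  under-dispersion must never shrink the SEs.
* **Profile likelihood**: bx_j ~ N(ξ_j, sx_j²), by_j ~ N(θξ_j, sy_j²)
  independent across SNPs. The nuisance means profile out analytically,
  leaving the one-dimensional objective
  g(θ) = Σ (by − θbx)²/(sy² + θ²sx²), minimised by bounded scalar search
  from three dispersed starts (deterministic and oracle-checkable; the
  test suite confirms agreement with a coarse-grid + refinement maximizer
  to 1e-6 on 100 random instances). The SE comes from the numerical
  curvature of the profile log-likelihood. Correlated sampling errors
  between the two legs (rho ≠ 0) are not supported.
* **Cochran's Q** over per-SNP ratios against the pooled estimate,
  χ² with J−1 df.
* **Diagnostics**: scatter (by vs bx), funnel (θ̂_j vs precision 1/se_j)
  and leave-one-out IVW tables, plot-ready; plotting itself is left to
  the caller.

All estimators are equivariant under rescaling of the exposure leg
(bx, sx → c·bx, c·sx multiplies causal estimates by 1/c), tested by
property-based checks.

## Metabolomics preprocessing

Feature intensities are log-transformed (zeros replaced by half the
feature's minimum positive value — a documented pseudo-count convention,
configurable), then batch-corrected per feature by residualizing on
categorical plate/date factors plus a linear acquisition-order drift and
restoring the grand mean (idempotent; post-adjustment plate means agree
to 1e-8). Filtering runs in a fixed order: retention time < 35 s →
between-duplicate Pearson correlation below threshold (default 0.5,
log scale, pairwise-complete) → masking of values beyond 3 sample SDs of
the feature mean → minimum non-missing count. Each removed feature
appears exactly once in the removal report with its reason; outlier
masking is value-level and reported as per-feature counts. SDs use the
n−1 denominator throughout. Standardization to mean 0, SD 1 drops
zero-variance features with a warning and is idempotent.

## The synthetic-data generator

The generator emulates the study conditions the estimators are meant for:

* Genotypes: independent SNPs in Hardy–Weinberg equilibrium,
  dosage ~ Binomial(2, RAF). The canonical IR score has 10 SNPs with RAFs
  0.2–0.5 and per-allele effects 0.04–0.12 SD (varying strengths, so that
  slope and intercept are separately identifiable in MR-Egger); the
  insulin-secretion score has 21 SNPs. The score explains ≈3% of exposure
  variance at the defaults — instrument strength is a tunable parameter,
  not a claim about any particular cohort.
* Exposure: X = Σ a_j G_j + b_U·U + e with a single standard-normal
  confounder U (loading 0.3 by default on both exposure and metabolite —
  enough to make observational and causal estimates diverge), then sample
  standardization. Residual SD solves for unit theoretical variance.
* Metabolites: M = θX + c_M·U + Σ d_j G_j + ε. The residual SD is chosen
  so the theoretical variance is 1 ("auto"), making θ itself the SD-unit
  causal effect; sample standardization is then a ≈1 rescaling that does
  not bias the mean estimate. Per-SNP direct effects d_j inject
  pleiotropy (constant d_j keeps InSIDE satisfied).
* Phenotypes: clamp M/I, OGTT insulin/glucose and covariates (age ≈ 71,
  sex, three genetic PCs, a two-level cohort label, BMI loading on the
  confounder) are monotone transforms of latent sensitivity/secretion
  variables chosen so the derived IGI30 and DI have the right sign
  structure and realistic scales (clamp M/I ≈ 5.4, DI ≈ 2.5). They are
  plumbing for the outcome-derivation code, not a physiologic model.
* Summary statistics: per-SNP true marginal effects from the generative
  model, reported beta ~ N(true, se) with se = 1/√(2f(1−f)n) for a
  unit-SD trait, with alleles and frequencies emitted so harmonization
  can be exercised.
* LC/MS-like feature tables: duplicate sample pairs, plate random
  intercepts and linear run-order drift additive on log intensity, a
  fraction of pure-noise features (low duplicate correlation) and of
  early-eluting features.

What the generator does **not** emulate: linkage disequilibrium between
instruments, genotype-imputation uncertainty, realistic mass-spectral
peak shapes or annotation ambiguity, non-normal metabolite distributions,
and population stratification beyond the cosmetic PC covariates. Passing
tests therefore demonstrate that the estimators and rules are implemented
correctly and are well calibrated under their stated assumptions — not
that those assumptions hold in any particular real cohort.

## Validation studies and problem sizes

The calibration module runs the package's own Monte-Carlo experiments,
all deterministic given a seed (child seeds drawn below 2³¹):

* Wald-ratio recovery: 500 two-sample replicates at n = 5,000 with
  θ = −0.4 and confounding 0.3 — mean estimate and 95% CI coverage.
* Null calibration: 500 replicates each for the Wald-ratio p at θ = 0 and
  the MR-Egger intercept p with no pleiotropy.
* Pleiotropy: 500 summary-level replicates with d = 0.05 and θ = 0; the
  Egger intercept should centre on 0.05 and the slope on 0, while IVW is
  displaced by the predictable amount d·Σwbx/Σwbx².
* FDR: 200 replicates of a 200-feature scan (20 true signals of 0.15 SD
  at n = 300) — empirical FDR against the 5% target.

These sizes keep each study in the tens of seconds on one CPU while
leaving Monte-Carlo error well below the effects being measured. The
worked-example reconstructions invert printed (estimate, 95% CI) pairs
into p-values; CI endpoints printed to two decimals propagate up to ~0.01
of rounding error into the reconstructed p, which is why agreement is
checked to printed precision only where the printed interval is wide
enough to support it.

## Known limitations

* No bidirectional or multivariable MR; no weighted-median or mode-based
  estimators; no correlated-instrument (LD-aware) generalization.
* No raw spectral processing, peak picking or annotation: the feature
  table is the entry point.
* The likelihood estimator assumes independent sampling errors between
  the exposure and outcome legs (rho = 0).
* Published summary results reconstructed from rounded print can be
  internally inconsistent under the normal approximation; the package
  reports what it computes and does not attempt to reverse-engineer
  upstream conventions.
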