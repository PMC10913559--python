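# Methods

## The model

A day of a child's life is treated as a 4-part composition
**x** = (MVPA, LPA, inactivity, sleep) of minutes summing to κ = 1440.
Compositions live on the simplex, so all analysis happens in isometric
log-ratio (ilr) coordinates built from a sequential binary partition in
*pivot* form: with parts (p₁, p₂, p₃, p₄) in basis order,

- ilr₁ = √(3/4) ln(p₁ / ∛(p₂p₃p₄))
- ilr₂ = √(2/3) ln(p₂ / √(p₃p₄))
- ilr₃ = √(1/2) ln(p₃ / p₄)

Four bases are used, one per behaviour placed first; only the first
coordinate of each is interpreted — the amount of its lead behaviour
*relative to the remaining three*. The identity ilr₁(j) = √(4/3)·clr_j
links the four bases: a single fit determines all four one-vs-rest
estimates, and their sum (divided by √(4/3)) is exactly zero. Both routes
are implemented and asserted equal, which is the package's main internal
consistency check.

The outcome model is multivariate ordinary least squares of the n×3 ilr
matrix on an intercept, one standardised exposure, and (in adjusted
models) sex, ethnicity (3 levels), maternal education (3 levels), maternal
age category (3 levels) and child BMI, categorical covariates dummy-coded
against a declared reference. Per-coordinate standard errors and t-based
95% CIs come from the univariate equivalents (the multivariate LS solution
coincides with the stacked univariate fits). The overall exposure test is
the Type II MANOVA Pillai trace V = tr(H(H+E)⁻¹), with H obtained by model
comparison (term dropped last; no interactions are modelled, so Type II
and Type III coincide) and the usual F approximation
s = min(3, q), m = (|3−q|−1)/2, n* = (N−rank(X)−4)/2. For a single-column
exposure the test is exact and equals Hotelling's T²; the test suite
checks both that identity and agreement with an independent MANOVA
implementation to 1e-10.

Estimated marginal means predict the ilr outcome at each exposure value
z ∈ {−2, …, +2} with every other design column at its sample mean (for
dummy columns, the sample proportion), then back-transform to minutes/day.
This equals the closure of x₀·exp(c·z) where c is the exposure's clr
coefficient vector and x₀ the covariate-averaged baseline — asserted
against that closed form in the tests. Because absolute EMM levels depend
on the covariate reference chosen, levels are comparable across exposures
within a run but not across studies that centre differently.

## Behaviour metrics

Epoch ENMO (milligravity) is classified as inactivity (< 35), LPA
(35–200) or MVPA (≥ 200); both cut-points are inclusive upward. Night
sleep windows are inputs (their detection from raw tri-axial signals is
upstream of this package and out of scope). Naps are maximal runs of
*waking* sub-35 mg epochs lasting ≥ 15 minutes, strictly consecutive — a
single interrupting epoch breaks the bout; this proxies posture-derived
sustained inactivity, which wrist ENMO cannot observe directly, and is a
documented divergence from posture-based nap calls. Total sleep = night +
naps. A midnight-to-midnight day is valid at ≥ 16 recorded hours
(inclusive); children need ≥ 2 valid weekdays and ≥ 1 valid weekend day;
the weekly composition is (5·weekday mean + 2·weekend mean)/7 per
behaviour, weighted before closure to 1440. Epoch length defaults to 5 s;
any divisor of 60 s works.

Zero minutes in a class are handled by multiplicative replacement
(δ = 1 min by default: zeros become δ, the rest shrink proportionally);
δ is a parameter so sensitivity to this choice can be probed.

## Questionnaire scoring

Each construct is scored by a one-factor maximum-likelihood model on the
item correlation matrix (scikit-learn's ML factor analysis is the
engine), loadings sign-fixed positive in sum, Heywood uniquenesses floored
at 0.005 with a warning. Scores are regression-method
(f = λ'Σ⁻¹z, Σ = λλ' + Ψ), standardised exactly in-sample; children with
missing items are scored from the observed sub-block of Σ, all-missing
rows get a missing score. Two-item constructs fall back to a standardised
mean. Ordinal responses are treated as numeric. Overall composites sum the
standardised construct scores (barriers negatively) and are
re-standardised, because exposures are interpreted per z-score unit.

## The synthetic generator

The generator encodes the study conditions, not a tuning surface:
n = 425 children; girls 48%; ethnicity 59/25/16% Chinese/Malay/Indian;
maternal education 31/34/35%; maternal age 22/41/37%; BMI 15.44 ± 1.95
kg/m²; baseline compositions 71/344/488/537 min (age 5.5 y) and
70/333/512/526 min (age 8 y — printed means sum to 1441 and are closed to
1440). Exposure effects are planted on the clr scale by converting a
published one-vs-rest quadruple: clr = pivots/√(4/3), re-centred to sum to
zero (absorbing print rounding). ilr residuals are Gaussian with sd 0.30
per coordinate (diagonal) — chosen once so simulated CI widths are of the
same order as the published ones; no residual covariance is published, so
recovery claims concern means only, never variances. Exposures are drawn
independent of covariates (no joint distribution is published).
Questionnaire items follow one-factor models with equal loadings implied
by the target α through r = α/(k − α(k−1)); four items per construct, α
0.82 for the parental and 0.91 for the environment constructs.

Epoch-level fixture days place the night window's sleep, emit any sleep
excess as ≥ 15-min still bouts (naps), and lay waking inactivity in runs
of ≤ 14 min separated by LPA/MVPA epochs so it can never be mistaken for
napping; per-class epoch counts are set by largest-remainder rounding, so
classification recovers the target within one epoch per class. Targets
whose sleep excess falls strictly between 0 and 15 min are rejected as
infeasible (they cannot survive the nap rule).

What the generator does **not** emulate: raw 80 Hz tri-axial waveforms,
device non-wear structure, attrition/missingness mechanisms, within-child
day-to-day autocorrelation, or exposure–covariate dependence. Passing
tests therefore demonstrate correctness of the estimators under the
assumed outcome model, not robustness to those real-data features.

## Numerical choices

- Natural logarithms throughout; closure constant κ = 1440 min,
  configurable.
- ilr round-trips asserted to 1e-9 min; clr re-centred after computation
  to kill floating-point drift; basis contrast matrices cached and checked
  orthonormal to 1e-12.
- Design rank is checked via QR and failures name the collinear columns.
- Significance threshold 0.05 two-sided; no multiple-testing correction
  across exposures.
- Group comparison tables use Pearson chi-square **without** continuity
  correction for categorical variables and pooled-variance Student t-tests
  for continuous ones; the uncorrected chi-square reproduces the published
  included-vs-excluded sex-distribution p-value at its printed rounding,
  the Yates-corrected variant does not.
- Validation experiments run at the study's sample size: the null
  rejection rate of the exposure Pillai test uses 2000 replicates of
  n = 425; planted-coefficient recovery uses 200 replicates (the
  Monte-Carlo error of the mean estimate is then ≈ 0.001, well inside the
  ±0.005 acceptance band). Both complete in seconds.

## Open design points resolved

- Ordering of the non-lead parts in each pivot basis is unpublished; the
  cyclic canonical order is used, and tests assert ilr₁ (hence all
  reported quantities) is invariant to it.
- Whether weekend weighting preceded closure is unpublished; weighting is
  applied per behaviour first, then the result closed.
- Whether overall composites were re-standardised after summation is
  unpublished; they are re-standardised here since effects are reported
  per z-score.
- CI method behind published per-behaviour intervals is unstated;
  per-coordinate t intervals are used.
- EMM covariate reference is unstated; sample means/proportions are used,
  so absolute minute levels may differ from other implementations even
  with identical coefficients.

## Limitations

Only D = 4 compositions with this partition family are supported. The
regression is cross-sectional per timepoint (no longitudinal or mixed
models, no mediation, no change-score analysis). CFA fit indices and
measurement-invariance testing are out of scope; the one-factor model is a
scoring engine, not a measurement-model validation.
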