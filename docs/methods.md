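# Methods

## Model and assumptions

`ttnorm` models serum total testosterone (TT, nmol/L) in healthy males as a
function of age. Three assumptions define the model:

1. **Log-adjustment.** Analyses run on `y = log10(TT + 1)`. The +1 offset
   makes zero TT map to zero (so curves can be anchored at the origin), and
   the log stabilises the strong level-dependence of TT variability. Base 10
   is the adopted convention; it is the base under which the published
   coefficient set reproduces the printed normative values (natural log does
   not, by an order of magnitude).
2. **Rational-polynomial mean.** The age-related mean of `y` is a ratio of
   polynomials in age with the denominator constant fixed at 1. A numerator
   of degree m and denominator of degree n has m+n+1 free parameters; the
   validated curve is cubic/cubic (7 parameters). Rational polynomials give
   a sharp pubertal rise and a long flat adult tail with few parameters, but
   are not uniquely parameterised near coefficient cancellation — so all
   recovery claims concern the *curve*, never the coefficients.
3. **Gaussian residuals with age-dependent spread.** Conditional on age,
   `y ~ N(mean(age), sigma(age))`. Centiles and z-scores follow analytically.
   An empirical-quantile mode is available for the extreme tails, where
   published normative tables are detectably asymmetric around the Gaussian
   prediction.

## Harmonization

Units are standardised with 1 ng/dL = 0.0347 nmol/L. Each immunoassay is
mapped to the LC-MS/MS scale by its published method-comparison equation
(linear for DPC, DSL, Centaur, Roche; the RIA comparison is published as a
power law `x = 0.706 y^1.077` and is inverted analytically). Conversions are
assumed to operate on nmol/L (units first, then assay), are applied exactly
once (converted rows are re-tagged as LC-MS/MS), and are clipped below at
zero since linear intercepts can push near-zero concentrations negative.
Records below age 3 are censored (boundary inclusive, so the age-3 normative
row remains in-domain). Zero-TT anchor points are appended at age 0 —
configurable, defaulting to 1% of the dataset — and carry a flag so that all
fit statistics exclude them while the fitting loss includes them at unit
weight.

## Fitting and model selection

Fits use Levenberg–Marquardt nonlinear least squares (`scipy.optimize.
least_squares`, method `lm`) with an analytic Jacobian, relative parameter
tolerance 1e-9 ("nine significant figures") and at most 4,000 iterations.
The numerator is initialised from an ordinary polynomial least-squares fit
with a flat denominator; candidate solutions whose denominator has a root in
[0, 105] years are rejected and refit from up to 20 seeded random restarts.
r² of a zero-variance target is defined as 0.

Complexity is selected by 5-fold cross-validation over 3–11 free parameters.
For a count n, the numerator takes degree ⌈(n−1)/2⌉ and the denominator
⌊(n−1)/2⌋ (so 7 → cubic/cubic). Within each fold, complexities are fitted in
increasing order and warm-started from the previous solution embedded in the
larger nested family; this keeps high-degree denominators pole-free and
makes nested-family training-error monotonicity hold in practice. The
selected count minimises mean held-out MSE, ties to the simpler model.
Complexities with failed folds are excluded from selection whenever any
complexity completed all folds, because a mean over fewer folds is not
comparable. A one-SE-style rule was considered and rejected in favour of the
plain minimum, which is the simplest reading of an "optimal trade-off"
criterion; with the parsimony tie-break it selects 7 parameters modally on
data generated from the 7-parameter truth.

The LOESS comparator is a tricube-weighted local polynomial smoother
(degree 1 or 2) evaluated on a 201-point age grid and interpolated back to
the data; "best LOESS" is the maximum r² over spans {0.2, 0.3, 0.5, 0.75} ×
degrees {1, 2}. The degree-1 variant is cross-checked against statsmodels
LOWESS in the test suite.

## Spread estimation and centiles

`sigma(age)` estimators: **kernel** (default) — Gaussian-kernel-weighted SD
centred at each query age, bandwidth 5 years (wide enough to hold ≥100
effective points per year of age at the pooled sample size, narrow enough to
resolve the post-40 rise); **binned** — SD per fixed-width age bin; and
**constant**. The packaged default profile is anchored to the published
2.5th/97.5th normative bands inverted under the Gaussian-in-log model
(sigma ≈ 0.151 at 19, 0.138 at 40, 0.173 at 88), linearly interpolated and
held constant beyond the anchors. A fourth anchor at age 3 (sigma ≈ 0.071)
is recovered one-sidedly from the 97.5th band because the 2.5th band is
clipped at zero there; without it the childhood rows of the normative table
are far too wide. Centile curves clip at zero — exactly as printed
childhood tables do — so the score-the-curve round trip is exact only where
clipping does not bind.

## Synthetic data

The generator emulates the pooled 13-study cross-sectional design: each
study contributes its published sample size and age median/range (total
n = 10,360; censoring at age 3 brings the modelling set near 10,100), ages
drawn from a Beta distribution scaled to [min, max] with total concentration
6 and shape solved so the median matches, log-adjusted TT drawn Gaussian
around a known mean curve (default: the validated model with constant
sigma = 0.15, the mid-range of the adult anchors), back-transformed, and
pushed through the *inverse* assay conversion onto each study's native
scale. A single integer seed drives deterministic per-study substreams.

What the generator does not emulate: digitization error, within-subject
longitudinal correlation, study-level mean offsets beyond the assay maps,
and non-Gaussian residual tails. Passing tests therefore demonstrate that
the pipeline recovers a known truth under its own distributional
assumptions, not that the published curve is correct for real populations.

Two interactions between the generator and the pipeline matter for testing.
First, the zero anchors assert y(0) = 0 while the generating truth has
y(0) ≈ 0.047, so curve-recovery tests harmonize with `anchor_count=0`; the
pipeline default keeps anchors, as the procedure intends for real data.
Second, clipping TT at zero truncates the Gaussian left tail at childhood
ages, so residual-Gaussianity checks sample adult ages where the clip never
binds.

## Numerical choices and problem sizes

- Denominator positivity is checked on a 0.1-year grid over [0, 105].
- Peak age is the argmax over integer ages 3–88, ties to the youngest.
- Zero-variance guards: ss_tot < 1e-12 defines a degenerate r², residual
  SD < 1e-12 a degenerate residual summary.
- Test problem sizes: full-pipeline tests run at the pooled design size
  (~10,360 records); the noiseless recovery test uses 2,000 points; the
  residual-proportion check uses 10⁶ draws; the selection-consistency
  property uses 10 replicates of the full design. Under noise at the study
  conditions the fitted curve deviates from truth by up to ~0.04–0.08 on
  the log-adjusted scale near the sparsely sampled pubertal knee (its
  least-squares optimum genuinely sits there; the fit's MSE is below the
  truth's), so recovery assertions bound the maximum log-scale deviation
  and the median relative deviation rather than demanding uniform
  few-percent agreement.

## Known limitations

- The real digitized dataset is not redistributable, so the published
  r² = 0.41 (and LOESS 0.32) are mirrored only as an ordering property on
  synthetic data.
- The extreme 1st/99th centile columns of published tables are not exactly
  reproducible under pure Gaussian z-scoring; the empirical-quantile mode
  narrows but does not close that gap.
- The model is undefined below age 3 and unvalidated above 88; the scoring
  CLI refuses ages outside [3, 88].
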