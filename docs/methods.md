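# Methods

## Model and estimation

The core quantity is the scaling exponent of an outcome count against
population on the log-log scale. The single-regime model
`ln Y = α + β ln N + ε` is ordinary least squares; the two-regime model
adds the hinge regressor `(ln N − ln k)·1[N > k]`, giving slope β₁ below
the knot population `k` and β₂ = β₁ + γ above it, with the fitted mean
continuous at `ln k` by construction. Natural logs are used throughout;
the slopes are invariant to the log base but intercepts and likelihoods
are not. Points exactly at the knot population sit on the below-knot side
(the hinge uses a strict inequality), and a valid spline fit requires at
least two points strictly on each side of the knot.

All inference is Gaussian OLS: 95% confidence intervals use the t
distribution with `n − p` degrees of freedom, and the interval for β₂
comes from the variance of the linear combination β₁ + γ using the
coefficient covariance matrix. The residual SD σ̂ uses the `n − p`
correction. Covariates (region dummies, or any numeric column) enter
additively on the log scale and never interact with `ln N`; categorical
covariates expand to dummies with the alphabetically first level as
reference.

## Knot selection and model comparison

The knot is profiled exhaustively: every observed population strictly
between the 5th and 95th population percentiles is a candidate (the grid
is configurable), each candidate's spline is scored by its maximized
Gaussian log-likelihood — a monotone transform of the residual sum of
squares, so the selection is the RSS argmin — and ties break toward the
smaller knot. Exhaustive search over observed values is exact at the
scale of hundreds of units and avoids the convergence ambiguities of
iterative segmented-regression schemes; the full likelihood profile is
returned for diagnostics. The profile loop evaluates each candidate's
RSS with a least-squares solve on the explicit three-column basis, then
the winning knot is refit through the standard spline path, which yields
the identical coefficients.

Model comparison uses `AIC = −2·loglik + 2·K` with the full Gaussian
log-likelihood (constants included) and `K` counting intercept, slopes,
covariates, **and σ**. Other conventions drop the constants or σ; deltas
between models on the same data are unaffected by the constants, and the
convention is stated so absolute AIC values are interpretable. Reported
confidence intervals condition on the selected knot; knot-selection
uncertainty is not propagated, a known limitation.

Regime labels come from the 95% CI: superlinear if the lower bound
exceeds 1, sublinear if the upper bound is below 1, otherwise linear.
The empirical percentile of a knot uses the midpoint rule,
`100·(#below + ½·#equal)/n`.

## Aggregation

County pill counts are summed over all member counties and all years of
the study window (default 2006–2014); unit population is the mean over
window years of the unit's annual county-population total. Any unit
containing a county in an excluded state (default AK and HI, the
non-contiguous states) is dropped entirely, and dropped units are logged,
so pill mass is conserved between input counties and retained-plus-
dropped units. Counties with pills but no crosswalk entry, or missing a
population in any window year, are hard errors — no silent imputation. A
unit spanning states in different census regions takes the region of the
state contributing the largest mean population; ties go to the
alphabetically first region with a warning. Units with zero pills cannot
enter a log-scale fit and are dropped at the log-log conversion with a
warning. FIPS codes are kept as zero-padded strings.

## Residual diagnostics

Residuals are observed minus fitted log-outcome; standardized residuals
divide by the fit's σ̂. The outlier rule flags `|z| ≥ 3` (configurable),
reporting sign separately, as a conventional 3σ screen. The smoother
diagnostic is a loess (lowess) fit of standardized residuals on
log-population, default span 0.75, evaluated on an even grid of at least
100 points over the observed range — a U-shaped curve indicates the
single power law is misspecified. Sensitivity refits exclude chosen units
with the knot either held fixed or re-searched on the reduced sample (the
new knot's population percentile is reported). The GeoJSON export writes
one feature per unit with residual, standardized residual and outlier
properties; units without geometry are reported and skipped rather than
failing the export. Geometries used in the analysis scripts are synthetic
grid squares — placeholders exercising the attribute join, not real unit
boundaries.

## Synthetic data

The generator inverts the analysis model: populations are drawn
log-uniform on [1e4, 2e7] (the commuting-zone range; log-normal and
Zipf-tail options exist for realism studies, but log-uniform gives even
leverage on both sides of the knot and is the default since the true
population law of the study sample is not part of the model), log
outcomes follow the continuous two-regime power law with additive
Gaussian noise, and counts are rounded to integers with a floor of one —
rounding perturbs `ln Y` at the `1/Y` level, negligible at realistic
magnitudes and tested at the noiseless limit. Default truth is
α = 5, β₁ = 1.36, β₂ = 0.92, k = 82,363, n = 607; the noise SD defaults
to 0.4, chosen to mimic the scatter of the observed log-log cloud.
Region labels are drawn with probabilities matching the study's regional
composition. Optional disaggregation splits each unit into counties —
symmetric Dirichlet population shares, multinomial pill shares
proportional to population — so aggregation inverts it exactly for pills
and within integer rounding for population. Outlier injection adds a
signed multiple of σ to the log outcome of randomly chosen units and
records their ids. Everything is bit-reproducible under the config seed;
derived stages (disaggregation, injection) use child seeds so they do not
perturb the unit draw.

What the generator does **not** emulate: spatial autocorrelation between
neighbouring units, temporal dynamics within the window, heteroskedastic
noise, and real CZ population frequencies. Recovery results therefore
validate the estimator under its own assumptions, not the field data.

## Recovery studies and problem sizes

The slope-recovery study fits the spline with the knot fixed at truth on
500 replicates of the default configuration and reports mean estimates
and 95%-CI coverage; the knot-recovery study runs the exhaustive search
on 200 replicates at noise SD 0.2 and reports the median selected knot.
Per-replicate seeds are spawned from one base seed via a seed sequence.
These sizes give Monte-Carlo standard errors well under the 0.02
tolerance used for the slope means while keeping the whole study around
ten seconds on one CPU.

Outlier plant-and-recover is probabilistic by nature: an injected unit's
own noise draw occasionally cancels part of a −5σ displacement, so exact
recovery of the planted set holds in most but not all replicates; the
test asserts a representative seeded run plus a majority rate over 50
seeds. The contamination-repair experiment uses gross contamination
(5 units at −20σ in samples of 100) because the exclusion benefit must
dominate sampling noise for a per-replicate comparison to be a sharp
test; the bias-to-noise ratio of milder contamination scales as
`|magnitude|·k/√n` and drops below detectability.

## Numerical notes

- Degenerate inputs (constant `x`, rank-deficient designs, knots outside
  the data range, strata too small to fit) raise hard errors or, for
  strata, are reported as skipped — never silently dropped.
- The oracle used in tests is a hand-written normal-equations solver with
  explicit summation, sharing no code path with the statsmodels-based
  fits it checks (1e-8 relative agreement on all fixtures).
- CSV round-trips keep pill counts as integers and populations at full
  float precision (shortest round-trip repr).
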