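# Methods

This note documents the models implemented in `sharkcast`, the choices
made where the design was genuinely open, and what the synthetic-data
tests do and do not demonstrate about real incident registries.

## Data model and scaling

An incident record carries a calendar year, a state/territory code
(NSW, QLD, WA, SA, VIC, TAS, NT, or `unknown`), a species label from a
closed set (white, tiger, bull, whaler, other, unknown; free-text names
such as "bronze whaler" and "dusky" are normalized to `whaler`), and
boolean fatality and provocation flags. The default study window is
1900 through 2019 inclusive (n = 120 fitted years): 2019 is the last
year of data and 2020 the first projection year. Records with an
unknown state count toward the national aggregate only, and the
national series is built by aggregating incidents, never by summing
state-level *rates*.

Rates are bites person⁻¹ year⁻¹: counts divided elementwise by the
region's population. Each regional rate series is made dimensionless by
dividing by its root mean square with an n−1 denominator,
`s = sqrt(Σ r²/(n−1))` — the convention of the standard scaling routine
in R when centring is disabled. The divisor is stored on the series, so
the transform is exactly invertible; projections are generated on the
scaled axis and multiplied back by `s` and the population projection
only at the end.

Regions with fewer than 100 incidents in the fitting window (a
configurable guard) are refused projection: with so few events the
trend and sinusoid fits are not trustworthy. In the bundled synthetic
country, SA is deliberately below this threshold.

## Trend models and ranking

Four nested mean structures — intercept-only, linear, quadratic, cubic
in year — are fitted to the scaled series by Gamma GLM with an identity
link. The year covariate is centred and scaled to unit variance before
polynomial expansion; raw calendar years cubed (≈10¹⁰) would make the
cubic design matrix numerically singular. Coefficients are reported in
both bases.

Model count `k` is the number of regression coefficients (degree + 1);
the Gamma shape parameter is profiled out at its conditional ML value
given the fitted means and is not counted. Ranking uses
AICc = −2LL + 2k + 2k(k+1)/(n−k−1) and Akaike weights computed via the
shifted-exponential form for numerical stability. Goodness of fit is
the percentage of deviance explained relative to the intercept-only
model; it is defined as 0 for the null model itself.

Two numerical choices of note:

* **Zeros.** The Gamma likelihood requires a strictly positive
  response; years with zero recorded bites are replaced by half the
  smallest positive value in that series. This preserves the series
  length and shape; dropping zeros instead is a configuration away but
  changes n across models.
* **Deterministic responses.** On an exactly constant or exactly
  polynomial series, iteratively reweighted least squares divides by a
  zero deviance; the implementation detects this and returns the exact
  least-squares solution (which is the ML fit for an identity link)
  with zero residual deviance. The profiled shape is bounded at e¹⁵ so
  the log-likelihood stays finite in this degenerate limit.

Diagnostics are standard: autocorrelation about the sample mean,
partial autocorrelation via the Durbin–Levinson recursion (both through
statsmodels), a smoothed FFT periodogram and a centred running mean.
The periodogram demeans (optionally detrends), normalizes one-sided so
the ordinates sum to n times the biased variance over the frequency
grid (spacing 1/n, frequencies in (0, 0.5]), and smooths with
successive modified Daniell kernels (uniform with half-weight
endpoints; default spans (3, 3); edges handled by reflection).

## Sinusoid fit and stochastic projection

The projection model is `y(x) = α + β·cos(γx + δ)` with `x = year −
1900`. Polynomial trends are deliberately *not* extrapolated: a cubic
that fits 120 years of data runs off to implausible values within a
decade of the data's edge, while the sinusoid encodes the multidecadal
rise-and-fall the diagnostics support.

Fitting exploits the model's partial linearity: for fixed γ the
remaining three parameters solve a linear least-squares problem
exactly, so a dense log-spaced grid of candidate periods (default 400,
from 4 years to 4n years) is scanned, and the best candidates are
refined jointly by Levenberg–Marquardt. The returned solution is
normalized to β ≥ 0, δ ∈ [0, 2π) and never has a larger SSE than its
initialization. The default minimum series length is 8; an override
(absolute floor 5, the parameter count plus one) exists for oracle
comparisons on tiny series.

Uncertainty is propagated by resampling observed residuals rather than
assuming a parametric error law, because the residual distributions are
skewed and sign-asymmetric:

* Residuals split into positive and negative pools. Exact zeros are
  assigned alternately (positive first, in year order) — the choice is
  arbitrary but deterministic, and keeps a run of zeros from starving
  one pool.
* Within each pool, every residual gets a resampling weight
  proportional to its own Gaussian-KDE density with Sheather–Jones
  solve-the-equation bandwidth. This follows the literal recipe of
  resampling observed residuals *weighted by* the fitted density;
  sampling from the KDE itself (i.e. adding kernel noise) is the
  natural alternative and is not the default.
* The Sheather–Jones selector is implemented in-package (pilot
  bandwidths 1.24·λ·n^(−1/7) and 1.23·λ·n^(−1/9) on the robust scale
  λ = min(sd, IQR/1.349), Gaussian φ⁴/φ⁶ functionals with diagonal
  terms, Brent root solve) and agrees with R's `bw.SJ(method="ste")` to
  ~1% on test samples; it falls back to Silverman's rule when the
  functional estimates are non-positive (very small or sparse pools).
* Residual magnitude varies systematically over the cycle: smaller in
  troughs, larger at peaks. This is captured by regressing \|residual\|
  on the sinusoid's fitted level per pool and scaling each drawn
  residual by the predicted magnitude at the projection year's level,
  normalized by the pool's mean prediction and floored at 0.1 so a
  hostile extrapolation can never flip a residual's sign or zero it
  out.
* Each projected iteration-year draws a pool with probability 0.5, a
  weighted residual with replacement, applies the magnitude scale, adds
  the sinusoid median, and floors the sum at zero (scaled rates cannot
  be negative). Draws are independent across years within an iteration;
  a consequence worth knowing is that *cumulative* totals over 47 years
  average over this noise and have much narrower intervals than any
  single year's band.

The default ensemble is 10 000 iterations; all randomness flows through
a seeded numpy generator and an unseeded projection is a configuration
error. Back-transformation multiplies by the stored RMS factor and the
yearly population projection, keeping counts continuous until reported
(public summaries round half away from zero).

## Deterrent scenarios

Deterrent effectiveness is Beta-distributed with mean 0.60 and SD 0.05,
moment-matched via ν = mean(1−mean)/sd² − 1 to shapes (57, 38). A draw
is taken per iteration-year by default (per-iteration draws, constant
over a trajectory, are an option). Averted bites are
`counts × effectiveness × uptake` on the uptake grid 0.1, …, 0.9, 1.0
(full uptake included because headline results are quoted for all
users). Averted counts are therefore exactly linear and monotone in
uptake within every iteration. Cumulative 2020–2066 summaries are
quantiles of per-iteration sums, not sums of per-year quantiles; on any
ensemble whose iterations cross ranks over years the two differ, and
only the former describes the uncertainty of a total.

## Under-reporting and abundance scenarios

Historical reporting is modelled as
`reporting(x) = γ + (1−γ)·logistic(α + β·ln x)` with calendar year x:
scenario A (γ = 0.602, α = −1601.064, β = 211.348) starts near 60%
recorded around 1900, inflects mid-century and saturates by the 1990s;
scenario B (γ = 0.394, α = −1381.997, β = 182.430) starts near 40% and
saturates during the 2000s. The natural logarithm is what places the
inflection near 1950 (α/β ≈ ln 1950). An alternative algebraic
arrangement of the same sigmoid, `1 − γ·logistic(α + β·ln x)`, is
retained behind `form="literal"` for comparison; with these parameter
values it is monotonically decreasing and inconsistent with the curves'
described behaviour, which is why the floor-logistic orientation is the
default. Correcting a series divides observed values by
`reporting(year)`, so corrected counts are never below observed;
thinning synthetic data by the same curve and correcting recovers the
generating expectation (an inverse pair, verified in tests).

Relative-abundance scenarios rest on the power law `r_b = N_rel^0.4307`
(the exponent is ln 2 / ln 5 to four decimals, i.e. a fivefold
abundance change doubles the bite rate). Species trajectories
(white, tiger, bull/whaler — the latter merged because whaler
attributions are frequently bull sharks) are supplied with maxima
scaled to 1. Each species' scaled series is multiplied by the fitted
mean of a Gamma log-link GLM of that series on its N_rel trajectory,
normalized by the fitted mean's average so a flat trajectory changes
nothing; the species sum, expressed as a proportion of its maximum,
then multiplies the total scaled series before the ordinary
sinusoid/projection path. The adjustment is multiplicative — the
additive reading of "using the linear forms of the coefficients" is
possible but breaks the no-adjustment limit — and note that a purely
multiplicative rescaling of a trajectory is absorbed by the log-link
fit: only shape changes in N_rel alter the result.

## Synthetic data: what it emulates, what it does not

The generator draws yearly counts as Poisson around
`(α + β·cos(γ(t−t₀) + δ)) × s × population(t)` — Poisson is the natural
rare-event count model; the real registry's generative process is
unknown. Species, fatality and provocation flags are independent
categorical/Bernoulli draws matching the published national composition
(20% fatal, 65% unprovoked, 31/21/14/6% white/tiger/bull/whaler, the
remainder split other/unknown); dependence between species and
fatality, spatial coordinates, within-year dates and victim/activity
fields are not modelled. The bundled country has four regions with
periods 85–110 years, geometric population growth from 1900 bases to
plausible present-day sizes, and per-capita scales chosen so the
national series averages about eight incidents per year, the historical
long-run average.

Passing recovery tests on these data shows the pipeline correctly
inverts its own generating process at realistic sample sizes — it does
not validate the sinusoidal hypothesis, the independence assumptions,
or constant reporting on real data. Where published headline figures
enter the tests at all, they do so only through arithmetic identities
(uptake linearity, Beta moment matching, the power-law exponent) that
hold regardless of the data.

## Problem sizes and reproducibility

Default problem sizes: 120 fitted years, 47 projection years, 10 000
ensemble iterations, 10-point uptake grid. Recovery suites use 100–200
replicates (trend ranking, period recovery) and 20 replicates at 2 000
iterations (band coverage). Every stochastic stage derives a child seed
deterministically from the single run seed (CRC32 of
`seed:region:stage`, kept below 2³¹), the run manifest records the
config hash, seeds and artifact checksums, and reruns with identical
configuration are byte-identical.

## Known limitations

* Exact reproduction of the published regional likelihood table is not
  attempted: the real incident file is not public, and likelihood
  conventions for the Gamma dispersion differ across software.
* The residual-magnitude model is one deliberate interpretation of a
  loosely specified "linear relationship" between residual size and the
  cycle; the covariate (fitted level), the normalization and the 0.1
  floor are documented choices, configurable but not exhaustive.
* Negative projected scaled rates are floored at zero; whether the
  original analysis floored or allowed them is unknown.
* Independent residual draws across years understate serial dependence
  in projected trajectories; cumulative-total intervals are accordingly
  narrow.
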