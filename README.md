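# sharkcast

Modelling and projection of per-capita shark-bite rates, and of the
number of bites that personal electronic deterrents could avert.

Shark bites are rare, but each one carries outsized human, social and
economic cost. Personal electronic deterrents — devices that project an
electric field around the wearer — reduce the probability of a bite by
roughly 60% in empirical trials. `sharkcast` asks the resulting policy
question quantitatively: *if a given fraction of water users wore such a
device, how many people would avoid being bitten over the coming
decades?* It is written for quantitative ecologists and risk analysts
working with national incident registries (year, state, species,
fatality and provocation flags) and yearly population series.

Because the Australian incident registry that motivates this pipeline
is not openly deposited, the package ships a first-class synthetic-data
generator that emulates it — regional incident tables with a known
sinusoidal per-capita structure, Poisson count noise, and the registry's
published composition (20% fatal, 65% unprovoked; 31/21/14/6% white,
tiger, bull and whaler sharks) — so every stage of the pipeline can be
validated against a known truth.

## The model

1. **Per-capita rates.** Yearly bite counts per region are divided by
   population to give bites person⁻¹ year⁻¹, then made dimensionless by
   dividing by the series' root mean square,
   `s = sqrt(Σ r² / (n−1))`, which is stored for exact inversion.
2. **Trend ranking.** Four nested polynomial mean structures
   (intercept, linear, quadratic, cubic in year) are fitted by Gamma GLM
   with identity link and ranked by AICc
   (`−2LL + 2k + 2k(k+1)/(n−k−1)`), with Akaike weights
   `wᵢ = exp(−Δᵢ/2)/Σⱼ exp(−Δⱼ/2)` and percent deviance explained.
   Diagnostics (ACF, Durbin–Levinson PACF, smoothed FFT periodogram,
   centred running means) probe the multidecadal periodicity that
   motivates the next step.
3. **Sinusoid + residual bootstrap.** The scaled series is summarized
   by `y = α + β·cos(γx + δ)` (least squares; polynomial trends are not
   extrapolated because they explode outside the data). Observed
   residuals are split by sign into two pools; each residual is weighted
   by its own Gaussian-KDE density (Sheather–Jones bandwidth); future
   years draw a sign with p = 0.5, then a weighted residual whose
   magnitude is scaled linearly with the sinusoid level (smaller in
   troughs, larger at peaks). 10 000 such trajectories, back-transformed
   through the stored RMS factor and the population projection, form the
   bite-count ensemble for 2020–2066.
4. **Bites averted.** Deterrent effectiveness is Beta-distributed,
   moment-matched to mean 0.60 and SD 0.05 (shapes 57 and 38); averted
   bites are `counts × effectiveness × uptake` for uptake proportions
   0.1–1.0, summarized per year and cumulatively (quantiles of
   per-iteration totals).
5. **Sensitivity scenarios.** Historical under-reporting curves
   `reporting(x) = γ + (1−γ)·logistic(α + β·ln x)` inflate the observed
   series before refitting; relative-abundance scenarios rescale
   species-specific series through the power law `r_b = N_rel^0.4307`
   (a fivefold abundance change doubles the bite rate).

## Worked example

```python
import numpy as np
from sharkcast.synthetic_data import simulate_country
from sharkcast.core_data import build_count_series, to_per_capita, rms_scale
from sharkcast.trend_models import rank_models
from sharkcast.projection import (fit_sinusoid, split_residuals,
    build_residual_sampler, project_ensemble, back_transform_to_counts)
from sharkcast.scenarios import (DeterrenceModel, averted_matrix,
    default_uptake_grid)

records, pops, truths = simulate_country(seed=42)
years = np.arange(1900, 2020)
counts = build_count_series(records, "AUS", years)
scaled = rms_scale(to_per_capita(counts, pops["AUS"].slice(years)))

print(rank_models(scaled).to_frame().round(3).to_string(index=False))

fit = fit_sinusoid(scaled)
print(f"sinusoid: alpha={fit.alpha:.3f} beta={fit.beta:.3f} "
      f"period={fit.period:.1f} yr delta={fit.delta:.2f}")

sampler = build_residual_sampler(split_residuals(scaled, fit))
ens = project_ensemble(fit, sampler, np.arange(2020, 2067),
                       n_iter=10_000, seed=42)
ens = back_transform_to_counts(ens, scaled.scale_factor, pops["AUS"])

averted = averted_matrix(ens, DeterrenceModel(), default_uptake_grid(),
                         seed=7)
s = averted.cumulative_summary()
j = list(s["uptake"]).index(1.0)
print(f"bites averted 2020-2066, full uptake: mean {s['mean'][j]:.0f} "
      f"(95% interval {s['lo'][j]:.0f}-{s['hi'][j]:.0f})")
```

Output:

```
      model      LL  k  dAICc  wAICc  pctDE
~yr+yr2+yr3 -41.310  4  0.000  0.852 13.712
        ~yr -45.583  2  4.301  0.099  7.509
    ~yr+yr2 -45.288  3  5.816  0.047  7.950
         ~1 -50.396  1 11.859  0.002  0.000
sinusoid: alpha=0.941 beta=0.208 period=117.7 yr delta=1.88
bites averted 2020-2066, full uptake: mean 828 (95% interval 750-906)
```

The ranking table reads like a standard information-theoretic model
comparison: the cubic trend is top-ranked for the national series
(wAICc 0.85), mirroring the short-term periodicity in the data. The
sinusoid summarizes the multidecadal cycle (~118-year wavelength on
this synthetic national aggregate). The final line is the headline
quantity: the mean (and 95% interval) of the number of people who would
avoid a bite between 2020 and 2066 if every water user wore a deterrent
with ~60% effectiveness.

The same pipeline is scriptable from the shell:

```sh
sharkcast simulate --seed 42 --out incidents.csv --pop population.csv
sharkcast fit --incidents incidents.csv --pop population.csv \
    --region AUS --out fits.json
sharkcast project --fits fits.json --pop population.csv \
    --n-iter 10000 --seed 42 --out ensemble.csv
sharkcast avert --ensemble ensemble.csv --seed 7 --out averted.csv
sharkcast run --config pipeline.yaml     # everything at once + figures
```

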