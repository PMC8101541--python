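"""Sinusoid fitting and stochastic residual-bootstrap projection.

The scaled per-capita bite-rate series is summarized by a sinusoid

    y(x) = alpha + beta * cos(gamma * x + delta),   x = year - year0,

fitted by least squares.  Uncertainty around the sinusoid median is then
propagated by resampling the observed fit residuals: positive and
negative residuals form separate pools, each residual is weighted by its
own Gaussian-KDE density (Sheather–Jones bandwidth), the sign of the
draw is a fair coin flip, and the drawn magnitude is scaled linearly
with the sinusoid's fitted level so residual spread shrinks in troughs
and grows at peaks, as in the observed series.  Summing many such draws
onto the sinusoid yields an ensemble of future scaled series that is
back-transformed to expected bite counts via the stored RMS factor and
the population projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .bandwidth import gaussian_kde_density, sheather_jones_bandwidth
from .core_data import PopulationSeries, ScaledRateSeries
from .errors import (
    AlignmentError,
    ConfigError,
    FitError,
    SamplerDegeneracyError,
)

DEFAULT_PROJECTION_YEARS = np.arange(2020, 2067)


@dataclass(frozen=True)
class SinusoidFit:
    """Least-squares sinusoid on a scaled rate series.

    ``alpha`` is the level, ``beta >= 0`` the amplitude, ``gamma`` the
    angular frequency in radians per year and ``delta`` the phase in
    [0, 2pi).  ``year0`` anchors the time covariate (x = year - year0).
    """

    region: str
    alpha: float
    beta: float
    gamma: float
    delta: float
    year0: int
    years: np.ndarray
    fitted: np.ndarray
    sse: float

    @property
    def period(self) -> float:
        """Wavelength in years (2pi / gamma)."""
        return 2.0 * np.pi / self.gamma

    def predict(self, years) -> np.ndarray:
        x = np.asarray(years, dtype=float) - self.year0
        return self.alpha + self.beta * np.cos(self.gamma * x + self.delta)


def _lin_solve(y, x, gamma):
    """For fixed gamma the model is linear in (alpha, b1, b2)."""
    design = np.column_stack(
        [np.ones_like(x), np.cos(gamma * x), np.sin(gamma * x)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return coef, float(resid @ resid)


def _to_amplitude_phase(b1, b2):
    # beta*cos(g x + d) = (beta cos d) cos(g x) - (beta sin d) sin(g x)
    beta = float(np.hypot(b1, b2))
    delta = float(np.arctan2(-b2, b1)) % (2.0 * np.pi)
    return beta, delta


def fit_sinusoid(scaled: ScaledRateSeries, n_grid: int = 400,
                 min_period: float = 4.0, max_period_factor: float = 4.0,
                 min_obs: int = 8) -> SinusoidFit:
    """Fit y = alpha + beta*cos(gamma*x + delta) by least squares.

    Initial angular frequencies come from a dense log-spaced grid of
    periods between ``min_period`` and ``max_period_factor * n`` years;
    for each candidate the remaining three parameters solve a linear
    least-squares problem exactly, and the best candidates are refined
    jointly with a trust-region solver.  The returned solution is
    normalized to beta >= 0 and delta in [0, 2pi) and its SSE never
    exceeds the best initialization's.
    """
    y = np.asarray(scaled.scaled, dtype=float)
    n = y.size
    if n < min_obs or n < 5:
        raise FitError(f"need at least {max(min_obs, 5)} observations, "
                       f"got {n}")
    if np.ptp(y) == 0.0:
        raise FitError("constant series has no sinusoidal structure")
    x = scaled.years.astype(float) - scaled.years[0]

    periods = np.geomspace(min_period, max_period_factor * n, n_grid)
    gammas = 2.0 * np.pi / periods
    trials = [(g, *_lin_solve(y, x, g)) for g in gammas]
    trials.sort(key=lambda t: t[2])

    def residual_fn(p):
        a, b1, b2, g = p
        return a + b1 * np.cos(g * x) + b2 * np.sin(g * x) - y

    best = None
    for g, coef, sse0 in trials[:5]:
        p0 = np.array([coef[0], coef[1], coef[2], g])
        try:
            sol = least_squares(residual_fn, p0, method="lm", xtol=1e-15,
                                ftol=1e-15, gtol=1e-15, max_nfev=5000)
        except Exception:
            continue
        sse = float(2.0 * sol.cost)
        cand = (min(sse, sse0), sol.x if sse <= sse0 else p0)
        if best is None or cand[0] < best[0]:
            best = cand
    if best is None:
        raise FitError(
            f"sinusoid optimization failed from all {len(trials[:5])} starts "
            f"(grid of {n_grid} periods)")

    sse, (alpha, b1, b2, gamma) = best
    gamma = abs(float(gamma))
    beta, delta = _to_amplitude_phase(b1, b2)
    fitted = alpha + beta * np.cos(gamma * x + delta)
    return SinusoidFit(region=scaled.region, alpha=float(alpha), beta=beta,
                       gamma=gamma, delta=delta, year0=int(scaled.years[0]),
                       years=scaled.years.copy(), fitted=fitted,
                       sse=float(sse))


@dataclass(frozen=True)
class ResidualPools:
    """Sign-partitioned residuals with the fitted level at each year.

    Zero residuals are assigned alternately (positive first, in year
    order) so a run of exact zeros cannot starve either pool.
    """

    positive: np.ndarray
    positive_fitted: np.ndarray
    negative: np.ndarray
    negative_fitted: np.ndarray

    @property
    def n(self) -> int:
        return self.positive.size + self.negative.size


def split_residuals(scaled: ScaledRateSeries, fit: SinusoidFit,
                    min_pool: int = 2) -> ResidualPools:
    """Partition observed-minus-fitted residuals by sign."""
    if not np.array_equal(scaled.years, fit.years):
        raise AlignmentError("fit years do not match the series years")
    resid = scaled.scaled - fit.fitted
    pos_v, pos_f, neg_v, neg_f = [], [], [], []
    next_zero_positive = True
    for r, f in zip(resid, fit.fitted):
        if r > 0:
            pos_v.append(r); pos_f.append(f)
        elif r < 0:
            neg_v.append(r); neg_f.append(f)
        elif next_zero_positive:
            pos_v.append(r); pos_f.append(f)
            next_zero_positive = False
        else:
            neg_v.append(r); neg_f.append(f)
            next_zero_positive = True
    pools = ResidualPools(np.asarray(pos_v), np.asarray(pos_f),
                          np.asarray(neg_v), np.asarray(neg_f))
    if len(pos_v) < min_pool or len(neg_v) < min_pool:
        raise SamplerDegeneracyError(
            f"residual pools too small (positive {len(pos_v)}, negative "
            f"{len(neg_v)}); consider pooling residuals or a longer series")
    return pools


@dataclass(frozen=True)
class _PoolSampler:
    values: np.ndarray
    weights: np.ndarray
    bandwidth: float
    slope: float        # |residual| ~ fitted-level regression
    intercept: float
    mean_predicted: float

    def scale_at(self, fitted_level: np.ndarray, floor: float) -> np.ndarray:
        pred = self.intercept + self.slope * np.asarray(fitted_level, float)
        return np.maximum(floor, pred / self.mean_predicted)


def _build_pool(values: np.ndarray, fitted: np.ndarray) -> _PoolSampler:
    if np.ptp(values) == 0.0:
        raise SamplerDegeneracyError(
            "all residuals in a pool are identical; bandwidth undefined")
    bw = sheather_jones_bandwidth(values)
    dens = gaussian_kde_density(values, values, bw)
    weights = dens / dens.sum()
    mag = np.abs(values)
    if np.ptp(fitted) == 0.0:
        slope, intercept = 0.0, float(mag.mean())
    else:
        slope, intercept = np.polyfit(fitted, mag, 1)
    mean_pred = float(np.mean(intercept + slope * fitted))
    if mean_pred <= 0:
        slope, intercept, mean_pred = 0.0, float(mag.mean()), float(mag.mean())
    return _PoolSampler(values=values, weights=weights, bandwidth=float(bw),
                        slope=float(slope), intercept=float(intercept),
                        mean_predicted=mean_pred)


@dataclass(frozen=True)
class ResidualSampler:
    """Weighted sign-mixture resampler of observed residuals.

    Each draw picks the positive pool with probability ``sign_prob``
    (a fair coin by default), then one of that pool's observed residuals
    with replacement, weighted by the KDE density at the residual itself.
    The drawn value is multiplied by the pool's magnitude scale, a linear
    function of the sinusoid level floored at ``scale_floor``.
    """

    positive: _PoolSampler
    negative: _PoolSampler
    sign_prob: float = 0.5
    scale_floor: float = 0.1


def build_residual_sampler(pools: ResidualPools, sign_prob: float = 0.5,
                           scale_floor: float = 0.1) -> ResidualSampler:
    if not (0.0 < sign_prob < 1.0):
        raise ConfigError("sign_prob must lie strictly between 0 and 1")
    if scale_floor <= 0:
        raise ConfigError("scale_floor must be positive")
    return ResidualSampler(
        positive=_build_pool(pools.positive, pools.positive_fitted),
        negative=_build_pool(pools.negative, pools.negative_fitted),
        sign_prob=sign_prob, scale_floor=scale_floor)


@dataclass(frozen=True)
class ProjectionEnsemble:
    """Iterations x years matrix of projected series for one region.

    ``units`` is ``"scaled"`` straight out of the projector and
    ``"counts"`` after back-transforming with the RMS factor and the
    population projection.
    """

    region: str
    years: np.ndarray
    matrix: np.ndarray      # shape (n_iter, n_years)
    units: str
    seed: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "years", np.asarray(self.years, dtype=int))
        object.__setattr__(self, "matrix", np.asarray(self.matrix, float))
        if self.matrix.ndim != 2 or self.matrix.shape[1] != self.years.size:
            raise AlignmentError("matrix shape does not match years")

    @property
    def n_iter(self) -> int:
        return self.matrix.shape[0]

    def quantiles(self, qs=(0.025, 0.5, 0.975)) -> np.ndarray:
        """Per-year quantiles across iterations, shape (len(qs), n_years)."""
        return np.quantile(self.matrix, qs, axis=0)


def project_ensemble(fit: SinusoidFit, sampler: ResidualSampler, years,
                     n_iter: int = 10_000, seed: int | None = None,
                     ) -> ProjectionEnsemble:
    """Generate the stochastic ensemble of future scaled series.

    For every iteration-year cell: flip the sign coin, draw a weighted
    residual from the matching pool, scale its magnitude by the sinusoid
    level for that year, add to the sinusoid median and floor at zero
    (scaled rates cannot be negative).  Draws are independent across
    cells and reproducible under a fixed seed.
    """
    if seed is None:
        raise ConfigError("projection requires an explicit seed")
    if n_iter < 1:
        raise ConfigError("n_iter must be >= 1")
    years = np.asarray(years, dtype=int)
    rng = np.random.default_rng(seed)
    median = fit.predict(years)

    pos, neg = sampler.positive, sampler.negative
    scale_pos = pos.scale_at(median, sampler.scale_floor)
    scale_neg = neg.scale_at(median, sampler.scale_floor)

    shape = (n_iter, years.size)
    take_pos = rng.random(shape) < sampler.sign_prob
    draw_pos = rng.choice(pos.values, size=shape, replace=True, p=pos.weights)
    draw_neg = rng.choice(neg.values, size=shape, replace=True, p=neg.weights)
    noise = np.where(take_pos, draw_pos * scale_pos, draw_neg * scale_neg)
    matrix = np.maximum(0.0, median[None, :] + noise)
    return ProjectionEnsemble(region=fit.region, years=years, matrix=matrix,
                              units="scaled", seed=seed)


def back_transform_to_counts(ensemble: ProjectionEnsemble, scale_factor: float,
                             pop: PopulationSeries) -> ProjectionEnsemble:
    """Scaled ensemble -> expected bite counts (kept continuous)."""
    if ensemble.units != "scaled":
        raise ConfigError(f"expected a scaled ensemble, got {ensemble.units}")
    pop = pop.slice(ensemble.years)
    counts = np.maximum(0.0, ensemble.matrix) * scale_factor * pop.population
    return ProjectionEnsemble(region=ensemble.region, years=ensemble.years,
                              matrix=counts, units="counts",
                              seed=ensemble.seed)
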