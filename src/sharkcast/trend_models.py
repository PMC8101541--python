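"""Polynomial trend models with Gamma errors, AICc ranking, diagnostics.

Four nested mean structures (intercept-only, linear, quadratic, cubic in
the year covariate) are fitted to the scaled per-capita rate series with
a Gamma error distribution and identity link, then ranked by the
small-sample Akaike information criterion.  The year covariate is
centred and rescaled to unit standard deviation before polynomial
expansion; raw calendar years cubed would make the design matrix
hopelessly ill-conditioned.

The Gamma shape parameter is profiled out at its maximum-likelihood
value given the fitted means and is not counted in k, so k equals the
number of regression coefficients (degree + 1).

Diagnostics: autocorrelation / partial autocorrelation (Durbin–Levinson)
and a smoothed FFT periodogram with modified Daniell kernels, plus a
centred running mean used to pre-smooth climate-index comparators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from numpy.polynomial import Polynomial
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

from .core_data import ScaledRateSeries
from .errors import ConfigError, DegenerateSeriesError, FitError

MAX_DEGREE = 3


@dataclass(frozen=True)
class TrendFit:
    """One polynomial Gamma-GLM fit on the scaled series."""

    degree: int
    coefficients: np.ndarray       # on the standardized year covariate
    coefficients_raw: np.ndarray   # on raw calendar year
    bse: np.ndarray                # standard errors (standardized basis)
    log_likelihood: float
    k: int
    n: int
    aicc: float
    pct_deviance_explained: float
    deviance: float
    null_deviance: float
    fitted: np.ndarray

    @property
    def label(self) -> str:
        return ("~1", "~yr", "~yr+yr2", "~yr+yr2+yr3")[self.degree]


@dataclass(frozen=True)
class ModelRanking:
    """AICc ranking of the four trend fits (ascending AICc)."""

    fits: tuple[TrendFit, ...]
    delta_aicc: np.ndarray
    waicc: np.ndarray

    @property
    def top(self) -> TrendFit:
        return self.fits[0]

    def to_frame(self) -> pd.DataFrame:
        """Ranking table: model, LL, k, dAICc, wAICc, %DE."""
        return pd.DataFrame({
            "model": [f.label for f in self.fits],
            "LL": [f.log_likelihood for f in self.fits],
            "k": [f.k for f in self.fits],
            "dAICc": self.delta_aicc,
            "wAICc": self.waicc,
            "pctDE": [f.pct_deviance_explained for f in self.fits],
        })


def handle_zeros(values: np.ndarray, policy: str = "half_min") -> np.ndarray:
    """Make a non-negative response strictly positive for Gamma fitting.

    ``half_min`` replaces zeros with half the smallest positive value in
    the series (preserves n and shape); ``drop`` is applied by the caller
    by masking instead.
    """
    values = np.asarray(values, dtype=float)
    if np.all(values > 0):
        return values
    positive = values[values > 0]
    if positive.size == 0:
        raise DegenerateSeriesError("all-zero response cannot be Gamma-fitted")
    if policy != "half_min":
        raise ConfigError(f"unknown zero policy {policy!r}")
    out = values.copy()
    out[out == 0] = positive.min() / 2.0
    return out


def _gamma_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    return float(2.0 * np.sum((y - mu) / mu - np.log(y / mu)))


def _gamma_profile_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    """Gamma log-likelihood maximized over the shape, means held fixed."""
    ratio = y / mu
    s = float(np.mean(np.log(ratio) - ratio))

    def nll(log_a):
        a = np.exp(log_a)
        return -(a * np.log(a) + a * s - np.log(y).sum() / y.size
                 - gammaln(a))

    res = minimize_scalar(nll, bounds=(-7.0, 15.0), method="bounded",
                          options={"xatol": 1e-10})
    a = np.exp(res.x)
    ll = (a * np.log(a) * y.size + a * (np.log(ratio) - ratio).sum()
          - np.log(y).sum() - gammaln(a) * y.size)
    return float(ll)


def _standardize_years(years: np.ndarray):
    mean = float(np.mean(years))
    sd = float(np.std(years, ddof=1))
    return (years - mean) / sd, mean, sd


def _raw_coefficients(coef: np.ndarray, mean: float, sd: float) -> np.ndarray:
    """Re-express a polynomial in z = (yr - mean)/sd on raw years."""
    poly = Polynomial(coef)(Polynomial([-mean / sd, 1.0 / sd]))
    out = np.zeros(len(coef))
    out[:len(poly.coef)] = poly.coef
    return out


def fit_polynomial_gamma(scaled: ScaledRateSeries, degree: int,
                         zero_policy: str = "half_min") -> TrendFit:
    """Fit one polynomial mean structure with Gamma errors, identity link."""
    if not (0 <= degree <= MAX_DEGREE):
        raise ConfigError(f"degree must be 0..{MAX_DEGREE}, got {degree}")
    y = handle_zeros(scaled.scaled, zero_policy)
    n = y.size
    if n <= degree + 2:
        raise FitError(f"series of length {n} too short for degree {degree}")
    z, mean, sd = _standardize_years(scaled.years.astype(float))
    exog = np.vander(z, degree + 1, increasing=True)
    null_dev = float(_gamma_deviance(y, np.full(n, y.mean())))

    ols = np.linalg.lstsq(exog, y, rcond=None)[0]
    ols_mu = exog @ ols
    if np.all(ols_mu > 0) and \
            np.max(np.abs(y - ols_mu)) <= 1e-10 * np.mean(y):
        # Deterministic response: the identity-link least-squares solution
        # is the ML fit and IRLS would divide by a zero deviance.
        coef, mu, dev = ols, ols_mu, 0.0
        bse = np.zeros_like(coef)
    else:
        import warnings

        starts = [np.r_[y.mean(), np.zeros(degree)]]
        if np.all(ols_mu > 0):
            starts.insert(0, ols)
        result, last_error = None, None
        with warnings.catch_warnings():
            # Identity link on Gamma is intentional here; statsmodels
            # warns that it does not respect the positive domain.
            warnings.simplefilter("ignore")
            model = sm.GLM(y, exog, family=sm.families.Gamma(
                link=sm.families.links.Identity()))
            for start in starts:
                try:
                    result = model.fit(start_params=start, maxiter=200)
                    break
                except Exception as exc:
                    last_error = exc
        if result is None:
            raise FitError(f"Gamma GLM (degree {degree}) failed: "
                           f"{last_error}") from last_error
        mu = np.asarray(result.mu)
        if not np.all(np.isfinite(mu)) or np.any(mu <= 0):
            raise FitError(f"Gamma GLM (degree {degree}) produced "
                           "non-positive fitted means")
        coef, dev = np.asarray(result.params), float(result.deviance)
        bse = np.asarray(result.bse)

    ll = _gamma_profile_loglik(y, mu)
    k = degree + 1
    pct_de = 0.0 if degree == 0 or null_dev == 0 else \
        100.0 * (null_dev - dev) / null_dev
    return TrendFit(degree=degree, coefficients=coef,
                    coefficients_raw=_raw_coefficients(coef, mean, sd),
                    bse=bse,
                    log_likelihood=ll, k=k, n=n, aicc=aicc(ll, k, n),
                    pct_deviance_explained=float(pct_de), deviance=dev,
                    null_deviance=null_dev, fitted=mu)


def aicc(log_likelihood: float, k: int, n: int) -> float:
    """Small-sample AIC: -2 LL + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ConfigError(f"AICc undefined for n={n}, k={k} (need n > k+1)")
    return -2.0 * log_likelihood + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aiccs) -> np.ndarray:
    """Model weights from AICc values via the shifted-exponential form."""
    aiccs = np.asarray(aiccs, dtype=float)
    if aiccs.size == 0 or not np.all(np.isfinite(aiccs)):
        raise ConfigError("AICc values must be a non-empty finite list")
    delta = aiccs - aiccs.min()
    w = np.exp(-0.5 * delta)
    return w / w.sum()


def rank_models(scaled: ScaledRateSeries,
                zero_policy: str = "half_min") -> ModelRanking:
    """Fit degrees 0..3 and rank by AICc; skips non-convergent fits."""
    fits, failures = [], []
    for degree in range(MAX_DEGREE + 1):
        try:
            fits.append(fit_polynomial_gamma(scaled, degree, zero_policy))
        except FitError as exc:
            failures.append((degree, str(exc)))
    if not fits:
        raise FitError(f"no trend model converged: {failures}")
    if failures:
        import warnings
        warnings.warn(f"ranking over convergent subset only; failed: "
                      f"{failures}", stacklevel=2)
    order = np.argsort([f.aicc for f in fits], kind="stable")
    fits = tuple(fits[i] for i in order)
    aiccs = np.array([f.aicc for f in fits])
    return ModelRanking(fits=fits, delta_aicc=aiccs - aiccs[0],
                        waicc=akaike_weights(aiccs))


# ---------------------------------------------------------------------------
# Periodicity diagnostics


@dataclass(frozen=True)
class DiagnosticsResult:
    """ACF/PACF and smoothed-periodogram output for one series."""

    lags: np.ndarray | None = None
    acf: np.ndarray | None = None
    pacf: np.ndarray | None = None
    frequencies: np.ndarray | None = None
    spectrum: np.ndarray | None = None
    spans: tuple[int, ...] | None = None


def acf_pacf(series, max_lag: int) -> DiagnosticsResult:
    """Autocorrelations (about the sample mean) and Durbin–Levinson PACF."""
    from statsmodels.tsa.stattools import acf as sm_acf, pacf as sm_pacf

    x = np.asarray(series, dtype=float)
    if np.ptp(x) == 0.0:
        raise DegenerateSeriesError("autocorrelation undefined for a "
                                    "constant series")
    if max_lag >= x.size / 2:
        raise ConfigError(f"max_lag {max_lag} must be < n/2 = {x.size / 2}")
    acf_vals = sm_acf(x, nlags=max_lag, fft=True)
    pacf_vals = sm_pacf(x, nlags=max_lag, method="ldb")
    return DiagnosticsResult(lags=np.arange(max_lag + 1), acf=acf_vals,
                             pacf=pacf_vals)


def _modified_daniell_kernel(span: int) -> np.ndarray:
    if span < 3 or span % 2 == 0:
        raise ConfigError(f"span must be an odd integer >= 3, got {span}")
    w = np.ones(span)
    w[0] = w[-1] = 0.5
    return w / w.sum()


def smoothed_periodogram(series, spans=(3, 3), detrend: bool = False,
                         ) -> DiagnosticsResult:
    """FFT periodogram smoothed with successive modified Daniell kernels.

    The raw ordinates are normalized one-sided so that their mean over
    the frequency grid (spacing 1/n) sums to the series' (biased)
    variance; smoothing redistributes but conserves that total up to
    edge effects (edges use reflection).
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 16:
        raise ConfigError(f"need n >= 16 for a periodogram, got {n}")
    x = x - x.mean()
    if detrend:
        t = np.arange(n, dtype=float)
        slope, intercept = np.polyfit(t, x, 1)
        x = x - (intercept + slope * t)

    fft = np.fft.rfft(x)
    k = np.arange(1, n // 2 + 1)
    power = np.abs(fft[k]) ** 2
    density = 2.0 * power / n
    if n % 2 == 0:
        density[-1] /= 2.0   # Nyquist bin is not doubled
    freqs = k / n

    for span in spans or ():
        kernel = _modified_daniell_kernel(int(span))
        pad = len(kernel) // 2
        padded = np.r_[density[pad - 1::-1], density, density[:-pad - 1:-1]]
        density = np.convolve(padded, kernel, mode="valid")
    return DiagnosticsResult(frequencies=freqs, spectrum=density,
                             spans=tuple(spans or ()))


def running_mean(series, window: int) -> np.ndarray:
    """Centred moving average; endpoints use shrinking windows."""
    if window % 2 == 0:
        raise ConfigError(f"window must be odd, got {window}")
    x = pd.Series(np.asarray(series, dtype=float))
    if window > len(x):
        raise ConfigError(f"window {window} exceeds series length {len(x)}")
    return (x.rolling(window, center=True, min_periods=1)
             .mean().to_numpy())
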