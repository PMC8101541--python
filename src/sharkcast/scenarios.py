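"""Intervention and bias scenarios applied around the projection engine.

Three scenario families:

* **Deterrent uptake** — personal electronic deterrents reduce the
  probability of a bite by about 60%; effectiveness is drawn from a Beta
  distribution moment-matched to mean 0.60, SD 0.05, and averted bites
  scale linearly with the proportion of water users wearing a device.
* **Under-reporting** — hypothetical historical reporting curves rising
  from a 1900 floor (60% or 40% of incidents recorded) to full reporting
  by the 1990s/2000s, used to inflate the observed series before
  refitting and reprojecting.
* **Relative shark abundance** — bite rate scales with relative
  abundance as a power law r_b = N_rel^0.4307 (a fivefold abundance
  change doubles the bite rate); species-specific abundance trajectories
  reshape the observed series before projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.special import expit

from .core_data import CountSeries, RateSeries, ScaledRateSeries
from .errors import ConfigError
from .projection import ProjectionEnsemble

#: Power-law exponent linking relative abundance to bite rate, the value
#: of ln 2 / ln 5 rounded to four decimals (fivefold abundance increase
#: <=> doubled bite rate).
ABUNDANCE_EXPONENT = 0.4307


def round_half_away(x):
    """Round to nearest integer with halves away from zero (92.5 -> 93)."""
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.floor(np.abs(x) + 0.5)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Deterrent effectiveness and uptake


def beta_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-match a Beta distribution to a mean and standard deviation."""
    if not (0.0 < mean < 1.0):
        raise ConfigError(f"mean must be in (0, 1), got {mean}")
    bound = mean * (1.0 - mean)
    if not (0.0 < sd * sd < bound):
        raise ConfigError(
            f"sd^2 must lie in (0, mean*(1-mean)) = (0, {bound:.6g}); "
            f"got sd={sd}")
    nu = bound / (sd * sd) - 1.0
    return mean * nu, (1.0 - mean) * nu


@dataclass(frozen=True)
class DeterrenceModel:
    """Beta-distributed probability that a deterrent prevents a bite."""

    effectiveness_mean: float = 0.60
    effectiveness_sd: float = 0.05

    @property
    def shapes(self) -> tuple[float, float]:
        return beta_params(self.effectiveness_mean, self.effectiveness_sd)


def default_uptake_grid() -> np.ndarray:
    """Uptake proportions 0.1 .. 0.9 plus full uptake."""
    return np.round(np.arange(1, 11) * 0.1, 10)


@dataclass(frozen=True)
class AvertedMatrix:
    """Bites averted: iterations x years x uptake proportions.

    ``averted[i, t, p] = counts[i, t] * effectiveness[i, t] * uptake[p]``,
    so averted counts are exactly linear and monotone in uptake.
    Cumulative totals over the projection window are computed per
    iteration first (sum over years), then summarized across iterations:
    quantiles of sums, not sums of quantiles.
    """

    region: str
    years: np.ndarray
    uptake: np.ndarray
    averted: np.ndarray          # (n_iter, n_years, n_uptake)
    seed: int | None = None

    @property
    def n_iter(self) -> int:
        return self.averted.shape[0]

    def yearly_summary(self, qs=(0.025, 0.5, 0.975)) -> np.ndarray:
        """Quantiles across iterations, shape (len(qs), n_years, n_uptake)."""
        return np.quantile(self.averted, qs, axis=0)

    def cumulative_totals(self) -> np.ndarray:
        """Per-iteration total averted over the window, (n_iter, n_uptake)."""
        return self.averted.sum(axis=1)

    def cumulative_summary(self, qs=(0.025, 0.975)) -> dict[str, np.ndarray]:
        """Mean and interval of the window total, per uptake proportion."""
        totals = self.cumulative_totals()
        lo, hi = np.quantile(totals, qs, axis=0)
        return {"uptake": self.uptake, "mean": totals.mean(axis=0),
                "median": np.median(totals, axis=0), "lo": lo, "hi": hi}


def averted_matrix(ensemble: ProjectionEnsemble, det: DeterrenceModel,
                   uptake, seed: int | None = None,
                   effect_per_iteration: bool = False) -> AvertedMatrix:
    """Bites averted under deterrent effectiveness and uptake scenarios.

    Effectiveness is drawn per iteration-year by default; with
    ``effect_per_iteration`` a single draw per iteration applies to all
    years of that trajectory.
    """
    if ensemble.units != "counts":
        raise ConfigError("averted_matrix needs a count-unit ensemble")
    if seed is None:
        raise ConfigError("averted_matrix requires an explicit seed")
    uptake = np.asarray(uptake, dtype=float)
    if uptake.size == 0:
        raise ConfigError("uptake grid is empty")
    if np.any(uptake <= 0) or np.any(uptake > 1) or np.any(np.diff(uptake) <= 0):
        raise ConfigError("uptake proportions must be strictly increasing "
                          "within (0, 1]")
    a, b = det.shapes
    rng = np.random.default_rng(seed)
    if effect_per_iteration:
        eff = rng.beta(a, b, size=(ensemble.n_iter, 1))
        eff = np.broadcast_to(eff, ensemble.matrix.shape)
    else:
        eff = rng.beta(a, b, size=ensemble.matrix.shape)
    averted = ensemble.matrix[:, :, None] * eff[:, :, None] * uptake[None, None, :]
    return AvertedMatrix(region=ensemble.region, years=ensemble.years,
                         uptake=uptake, averted=averted, seed=seed)


# ---------------------------------------------------------------------------
# Under-reporting


@dataclass(frozen=True)
class ReportingScenario:
    """Sigmoidal historical reporting proportion.

    ``reporting(x) = floor + (1 - floor) * logistic(alpha + beta*ln x)``
    with x the calendar year: the proportion of incidents actually
    recorded rises from ``floor`` around 1900 through a mid-century
    inflection to full reporting late in the 20th century.  The
    ``literal`` form ``1 - floor / (1 + exp(-alpha - beta*ln x))`` is
    retained for comparison; it is monotonically decreasing with these
    parameter values and does not match the curves' described behaviour.
    """

    scenario_id: str
    gamma_floor: float
    alpha_r: float
    beta_r: float

    def __post_init__(self):
        if not (0.0 < self.gamma_floor < 1.0):
            raise ConfigError("gamma_floor must be in (0, 1)")


#: Reporting floor 60% at 1900, full reporting by the 1990s.
SCENARIO_A = ReportingScenario("A", gamma_floor=0.602, alpha_r=-1601.064,
                               beta_r=211.348)
#: Reporting floor 40% at 1900, full reporting during the 2000s.
SCENARIO_B = ReportingScenario("B", gamma_floor=0.394, alpha_r=-1381.997,
                               beta_r=182.430)

REPORTING_SCENARIOS = {"A": SCENARIO_A, "B": SCENARIO_B}


def reporting_proportion(year, scenario: ReportingScenario,
                         form: str = "floor_logistic"):
    """Proportion of incidents recorded in a given calendar year."""
    x = np.asarray(year, dtype=float)
    if np.any(x < 1800):
        raise ConfigError("reporting curves are defined for years >= 1800")
    z = scenario.alpha_r + scenario.beta_r * np.log(x)
    if form == "floor_logistic":
        out = scenario.gamma_floor + (1.0 - scenario.gamma_floor) * expit(z)
    elif form == "literal":
        out = 1.0 - scenario.gamma_floor * expit(z)
    else:
        raise ConfigError(f"unknown reporting form {form!r}")
    return out if out.ndim else float(out)


def correct_for_reporting(series, scenario: ReportingScenario,
                          form: str = "floor_logistic"):
    """Inflate an observed series by the reporting proportion per year.

    Accepts a :class:`CountSeries` or :class:`RateSeries` and returns the
    same type with values divided by ``reporting(year)`` (so corrected
    values are always >= observed).
    """
    rep = reporting_proportion(series.years, scenario, form=form)
    if isinstance(series, CountSeries):
        return CountSeries(series.region, series.years, series.counts / rep)
    if isinstance(series, RateSeries):
        return RateSeries(series.region, series.years, series.rate / rep)
    raise ConfigError(
        f"cannot correct a {type(series).__name__}; pass counts or rates")


# ---------------------------------------------------------------------------
# Relative abundance


def abundance_rate_factor(n_rel, exponent: float = ABUNDANCE_EXPONENT):
    """Relative bite rate implied by relative abundance: N_rel**0.4307."""
    n_rel = np.asarray(n_rel, dtype=float)
    if np.any(n_rel <= 0):
        raise ConfigError("relative abundance must be positive")
    out = n_rel ** exponent
    return out if out.ndim else float(out)


ABUNDANCE_SPECIES = ("white", "tiger", "bull_whaler")


@dataclass(frozen=True)
class AbundanceScenario:
    """Species relative-abundance trajectories, maxima scaled to 1."""

    years: np.ndarray
    n_rel: Mapping[str, np.ndarray]
    exponent: float = ABUNDANCE_EXPONENT

    def __post_init__(self):
        object.__setattr__(self, "years", np.asarray(self.years, dtype=int))
        missing = [s for s in ABUNDANCE_SPECIES if s not in self.n_rel]
        if missing:
            raise ConfigError(f"abundance scenario missing species: {missing}")
        for s, traj in self.n_rel.items():
            traj = np.asarray(traj, dtype=float)
            if traj.shape != self.years.shape:
                raise ConfigError(f"N_rel for {s} does not align with years")
            if np.any(traj <= 0) or np.any(traj > 1.0 + 1e-12):
                raise ConfigError(f"N_rel for {s} must lie in (0, 1]")


def _gamma_loglink_prediction(y: np.ndarray, n_rel: np.ndarray) -> np.ndarray:
    """Fitted mean from a Gamma log-link GLM of the series on N_rel."""
    import statsmodels.api as sm

    from .trend_models import handle_zeros

    y = handle_zeros(y)
    exog = np.column_stack([np.ones_like(n_rel), n_rel])
    model = sm.GLM(y, exog, family=sm.families.Gamma(
        link=sm.families.links.Log()))
    result = model.fit(maxiter=200)
    return np.asarray(result.mu)


def species_abundance_adjustments(
        species_series: Mapping[str, ScaledRateSeries],
        scenario: AbundanceScenario) -> dict[str, np.ndarray]:
    """Per-species abundance-adjusted scaled series.

    Each species' observed series is multiplied by its Gamma log-link
    fitted mean response to N_rel, normalized to the fitted mean's
    average so a flat trajectory changes nothing.  Species are treated
    independently: altering one trajectory never touches the others.
    """
    out = {}
    for sp in ABUNDANCE_SPECIES:
        series = species_series[sp]
        if not np.array_equal(series.years, scenario.years):
            raise ConfigError(f"species series {sp} does not align with the "
                              "abundance scenario years")
        n_rel = np.asarray(scenario.n_rel[sp], dtype=float)
        pred = _gamma_loglink_prediction(series.scaled, n_rel)
        out[sp] = series.scaled * (pred / pred.mean())
    return out


def adjust_series_for_abundance(
        species_series: Mapping[str, ScaledRateSeries],
        scenario: AbundanceScenario,
        total: ScaledRateSeries) -> ScaledRateSeries:
    """Reshape the total scaled series by species abundance trajectories.

    Per species: a Gamma log-link GLM of the species' scaled bite rate on
    its N_rel trajectory gives a fitted mean response; the observed
    species series is rescaled multiplicatively by the fitted mean
    (normalized to its own average, so a flat trajectory leaves the
    series untouched).  Species series are then summed, the sum is
    expressed as a proportion of its maximum, and that proportional
    series multiplies the total scaled series.  The result keeps the
    total's scale factor and feeds the ordinary sinusoid/projection path.
    """
    missing = [s for s in ABUNDANCE_SPECIES if s not in species_series]
    if missing:
        raise ConfigError(f"missing species series: {missing}")
    adjusted = species_abundance_adjustments(species_series, scenario)
    adjusted_sum = np.sum([adjusted[sp] for sp in ABUNDANCE_SPECIES], axis=0)
    proportional = adjusted_sum / adjusted_sum.max()
    return ScaledRateSeries(total.region, total.years,
                            total.scaled * proportional, total.scale_factor)
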