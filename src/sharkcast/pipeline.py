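"""End-to-end orchestration: simulate → fit → project → avert → report.

A single configuration drives the whole pipeline per region: build the
per-capita scaled series, rank the polynomial trend models, fit the
sinusoid, bootstrap the residuals into a projection ensemble,
back-transform to expected bite counts, and convert to averted-bite
matrices under the deterrent scenario.  All stochastic stages draw
reproducible seeds derived from the single run seed, and a manifest
records seeds and artifact checksums so a run can be replayed exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import core_data
from .core_data import (
    AUS,
    CountSeries,
    PopulationSeries,
    ScaledRateSeries,
    build_count_series,
    filter_incidents,
    read_incidents,
    read_population,
    rms_scale,
    to_per_capita,
)
from .errors import ConfigError, SamplerDegeneracyError
from .projection import (
    ProjectionEnsemble,
    SinusoidFit,
    back_transform_to_counts,
    build_residual_sampler,
    fit_sinusoid,
    project_ensemble,
    split_residuals,
)
from .scenarios import (
    AvertedMatrix,
    DeterrenceModel,
    REPORTING_SCENARIOS,
    averted_matrix,
    correct_for_reporting,
    default_uptake_grid,
    round_half_away,
)
from .trend_models import ModelRanking, rank_models

logger = logging.getLogger("sharkcast")

DEFAULT_REGIONS = (AUS, "NSW", "QLD", "WA")


def stage_seed(seed: int, region: str, stage: str) -> int:
    """Stable per-(region, stage) child seed below 2**31."""
    return zlib.crc32(f"{seed}:{region}:{stage}".encode()) % (2 ** 31)


@dataclass
class PipelineConfig:
    """Flat configuration mirroring the YAML document."""

    incidents: str
    population: str
    outdir: str
    seed: int
    regions: tuple[str, ...] = DEFAULT_REGIONS
    filter_preset: str = "all"
    fit_window: tuple[int, int] = (1900, 2019)
    projection_window: tuple[int, int] = (2020, 2066)
    n_iter: int = 10_000
    effect_mean: float = 0.60
    effect_sd: float = 0.05
    uptake: tuple[float, ...] = tuple(default_uptake_grid())
    reporting_scenario: str | None = None
    min_incidents: int = 100
    make_plots: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("regions", "uptake", "fit_window", "projection_window"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        """Aggregate every configuration problem before any stage runs."""
        problems = []
        for name in ("incidents", "population"):
            if not Path(getattr(self, name)).exists():
                problems.append(f"{name} file not found: {getattr(self, name)}")
        if self.seed is None:
            problems.append("seed is mandatory for stochastic stages")
        f0, f1 = self.fit_window
        p0, p1 = self.projection_window
        if f1 >= p0:
            problems.append(
                f"projection window {p0}–{p1} overlaps fit window {f0}–{f1}")
        if p0 != f1 + 1:
            problems.append(
                f"projection window must start the year after the fit window "
                f"ends ({f1 + 1}), got {p0}")
        if self.n_iter < 1:
            problems.append("n_iter must be >= 1")
        if self.filter_preset not in core_data.FILTER_PRESETS:
            problems.append(f"unknown filter preset {self.filter_preset!r}")
        if self.reporting_scenario is not None and \
                self.reporting_scenario not in REPORTING_SCENARIOS:
            problems.append(
                f"unknown reporting scenario {self.reporting_scenario!r}")
        if problems:
            raise ConfigError("invalid pipeline config: " + "; ".join(problems))

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


@dataclass
class RegionResult:
    """Everything the pipeline computed for one region."""

    region: str
    counts: CountSeries
    scaled: ScaledRateSeries
    ranking: ModelRanking
    sinusoid: SinusoidFit
    ensemble_counts: ProjectionEnsemble
    averted: AvertedMatrix
    truth_note: str | None = None


@dataclass
class RunManifest:
    """Replay record: config hash, seeds and artifact checksums."""

    config_hash: str
    seed: int
    stage_seeds: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)
    skipped_regions: dict = field(default_factory=dict)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_region(records, populations: Mapping[str, PopulationSeries],
               region: str, config: PipelineConfig) -> RegionResult:
    """Run every modelling stage for one region."""
    fit_years = np.arange(config.fit_window[0], config.fit_window[1] + 1)
    proj_years = np.arange(config.projection_window[0],
                           config.projection_window[1] + 1)
    filtered = filter_incidents(records, config.filter_preset)
    counts = build_count_series(filtered, region, fit_years)
    total = counts.counts.sum()
    if total < config.min_incidents:
        raise SamplerDegeneracyError(
            f"{region}: only {total:.0f} incidents in the fitting window "
            f"(< {config.min_incidents}); model fits would be dubious")
    if region not in populations:
        raise ConfigError(f"no population series for region {region}")
    if config.reporting_scenario is not None:
        scenario = REPORTING_SCENARIOS[config.reporting_scenario]
        counts = correct_for_reporting(counts, scenario)
    rates = to_per_capita(counts, populations[region].slice(fit_years))
    scaled = rms_scale(rates)
    ranking = rank_models(scaled)
    sinusoid = fit_sinusoid(scaled)
    sampler = build_residual_sampler(split_residuals(scaled, sinusoid))
    ens_scaled = project_ensemble(
        sinusoid, sampler, proj_years, n_iter=config.n_iter,
        seed=stage_seed(config.seed, region, "project"))
    ens_counts = back_transform_to_counts(
        ens_scaled, scaled.scale_factor, populations[region])
    det = DeterrenceModel(config.effect_mean, config.effect_sd)
    averted = averted_matrix(
        ens_counts, det, np.asarray(config.uptake),
        seed=stage_seed(config.seed, region, "avert"))
    logger.info("region=%s incidents=%d top_model=%s period=%.1f n_iter=%d",
                region, int(total), ranking.top.label, sinusoid.period,
                config.n_iter)
    return RegionResult(region=region, counts=counts, scaled=scaled,
                        ranking=ranking, sinusoid=sinusoid,
                        ensemble_counts=ens_counts, averted=averted)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages for every configured region and write artifacts."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = read_incidents(config.incidents, window=config.fit_window)
    populations = read_population(config.population)

    manifest = RunManifest(config_hash=config.config_hash(), seed=config.seed)
    results: dict[str, RegionResult] = {}
    for region in config.regions:
        try:
            results[region] = run_region(records, populations, region, config)
            manifest.stage_seeds[region] = {
                "project": stage_seed(config.seed, region, "project"),
                "avert": stage_seed(config.seed, region, "avert")}
        except SamplerDegeneracyError as exc:
            manifest.skipped_regions[region] = str(exc)
            logger.warning("skipping %s: %s", region, exc)
    if not results:
        raise ConfigError("no region had enough data to model")

    paths = write_report(results, outdir, config)
    manifest.artifacts = {p.name: _sha256(p) for p in paths}
    manifest.write(outdir / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# Artifact writing


def ranking_table(results: Mapping[str, RegionResult]) -> pd.DataFrame:
    frames = []
    for region, res in results.items():
        frame = res.ranking.to_frame()
        frame.insert(0, "region", region)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def sinusoid_table(results: Mapping[str, RegionResult]) -> pd.DataFrame:
    rows = []
    for region, res in results.items():
        s = res.sinusoid
        rows.append({"region": region, "alpha": s.alpha, "beta": s.beta,
                     "gamma": s.gamma, "delta": s.delta,
                     "period_years": s.period, "sse": s.sse,
                     "scale_factor": res.scaled.scale_factor})
    return pd.DataFrame(rows)


def averted_summary_table(res: RegionResult) -> pd.DataFrame:
    """One row per (year, uptake): median and 95% interval of averted."""
    lo, med, hi = res.averted.yearly_summary()
    rows = []
    for j, p in enumerate(res.averted.uptake):
        for i, year in enumerate(res.averted.years):
            rows.append({"region": res.region, "year": int(year),
                         "uptake": float(p), "median": med[i, j],
                         "lo95": lo[i, j], "hi95": hi[i, j]})
    return pd.DataFrame(rows)


def cumulative_table(res: RegionResult) -> pd.DataFrame:
    """Total averted over the window per uptake: mean and 95% interval.

    Quantiles are taken over per-iteration totals (sum over years within
    each trajectory), not sums of per-year quantiles.
    """
    summary = res.averted.cumulative_summary()
    return pd.DataFrame({
        "region": res.region,
        "uptake": summary["uptake"],
        "mean": summary["mean"],
        "median": summary["median"],
        "lo95": summary["lo"],
        "hi95": summary["hi"],
        "mean_rounded": round_half_away(summary["mean"]),
        "lo95_rounded": round_half_away(summary["lo"]),
        "hi95_rounded": round_half_away(summary["hi"]),
    })


def write_report(results: Mapping[str, RegionResult], outdir: Path,
                 config: PipelineConfig) -> list[Path]:
    """Write ranking/sinusoid/averted tables and per-region figures."""
    outdir = Path(outdir)
    paths = []

    def _save(frame: pd.DataFrame, name: str):
        path = outdir / name
        frame.to_csv(path, index=False)
        paths.append(path)

    _save(ranking_table(results), "trend_ranking.csv")
    _save(sinusoid_table(results), "sinusoid_fits.csv")
    _save(pd.concat([averted_summary_table(r) for r in results.values()],
                    ignore_index=True), "averted_yearly.csv")
    _save(pd.concat([cumulative_table(r) for r in results.values()],
                    ignore_index=True), "averted_cumulative.csv")

    ens_rows = []
    for region, res in results.items():
        lo, med, hi = res.ensemble_counts.quantiles()
        ens_rows.append(pd.DataFrame({
            "region": region, "year": res.ensemble_counts.years,
            "median": med, "lo95": lo, "hi95": hi}))
    _save(pd.concat(ens_rows, ignore_index=True), "projected_counts.csv")

    if config.make_plots:
        paths.extend(_write_figures(results, outdir, config))
    return paths


def _write_figures(results, outdir: Path, config: PipelineConfig) -> list[Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = []
    for region, res in results.items():
        fig, axes = plt.subplots(1, 2, figsize=(11, 4))
        lo, med, hi = res.ensemble_counts.quantiles()
        years = res.ensemble_counts.years
        axes[0].fill_between(years, lo, hi, alpha=0.3, color="tab:red",
                             label="95% ensemble band")
        axes[0].plot(years, med, color="tab:red", label="median projection")
        axes[0].plot(res.counts.years, res.counts.counts, color="k", lw=0.8,
                     label="observed counts")
        axes[0].set(title=f"{region}: bites year$^{{-1}}$ (seed "
                          f"{config.seed})", xlabel="year", ylabel="bites")
        axes[0].legend(fontsize=7)

        alo, amed, ahi = res.averted.yearly_summary()
        for j, p in enumerate(res.averted.uptake):
            axes[1].plot(years, amed[:, j], label=f"uptake {p:.1f}")
        axes[1].set(title=f"{region}: median bites averted year$^{{-1}}$",
                    xlabel="year", ylabel="averted")
        axes[1].legend(fontsize=6, ncol=2)
        fig.tight_layout()
        path = outdir / f"projection_{region}.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# JSON fit artifacts (used by the CLI's fit/project split)


def fits_to_json(scaled: ScaledRateSeries, ranking: ModelRanking,
                 sinusoid: SinusoidFit, path) -> None:
    payload = {
        "region": scaled.region,
        "years": scaled.years.tolist(),
        "scaled": scaled.scaled.tolist(),
        "scale_factor": scaled.scale_factor,
        "glm_ranking": ranking.to_frame().to_dict(orient="records"),
        "sinusoid": {"alpha": sinusoid.alpha, "beta": sinusoid.beta,
                     "gamma": sinusoid.gamma, "delta": sinusoid.delta,
                     "year0": sinusoid.year0, "sse": sinusoid.sse},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def fits_from_json(path) -> tuple[ScaledRateSeries, SinusoidFit]:
    with open(path) as fh:
        payload = json.load(fh)
    scaled = ScaledRateSeries(payload["region"],
                              np.asarray(payload["years"], dtype=int),
                              np.asarray(payload["scaled"], dtype=float),
                              payload["scale_factor"])
    s = payload["sinusoid"]
    x = scaled.years.astype(float) - s["year0"]
    fitted = s["alpha"] + s["beta"] * np.cos(s["gamma"] * x + s["delta"])
    sinusoid = SinusoidFit(region=payload["region"], alpha=s["alpha"],
                           beta=s["beta"], gamma=s["gamma"], delta=s["delta"],
                           year0=s["year0"], years=scaled.years,
                           fitted=fitted, sse=s["sse"])
    return scaled, sinusoid
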