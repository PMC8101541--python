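"""Incident and population data: reading, validation, filtering and scaling.

The analysis works on yearly per-capita bite rates (bites person⁻¹ year⁻¹)
by region, made dimensionless by dividing each regional series by its root
mean square.  The RMS divisor is stored so the transform is exactly
invertible, which matters because projections are generated on the scaled
axis and only converted back to expected bite counts at the end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    DegenerateSeriesError,
    FormatError,
    ValidationError,
)

#: State/territory codes accepted for individual incidents.
REGION_CODES = ("NSW", "QLD", "WA", "SA", "VIC", "TAS", "NT")

#: Pseudo-region meaning "all of Australia"; only valid as an aggregation
#: target, never as a record's own region.
AUS = "AUS"

#: Records whose state could not be established.  They are retained and
#: count toward the national aggregate only.
UNKNOWN_REGION = "unknown"

SPECIES_LABELS = ("white", "tiger", "bull", "whaler", "other", "unknown")

#: Common free-text species names mapped onto the closed label set.
#: Bronze whalers and duskies are grouped as "whaler"; they are merged
#: with bull sharks only inside abundance scenarios, not here.
SPECIES_ALIASES = {
    "bronze whaler": "whaler",
    "dusky": "whaler",
    "dusky whaler": "whaler",
    "white pointer": "white",
    "great white": "white",
}

#: Default study window: 1900 up to the start of 2020, so 2019 is the last
#: fitted year and 2020 the first projection year.
DEFAULT_WINDOW = (1900, 2019)

_TRUE = {"1", "true", "t", "yes", "y"}
_FALSE = {"0", "false", "f", "no", "n"}


def _parse_bool(raw: object) -> bool:
    text = str(raw).strip().lower()
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise ValueError(f"not a boolean: {raw!r}")


@dataclass(frozen=True)
class IncidentRecord:
    """One recorded shark–human interaction."""

    year: int
    region: str
    species: str
    fatal: bool
    provoked: bool

    def __post_init__(self):
        if self.region not in REGION_CODES and self.region != UNKNOWN_REGION:
            raise ValueError(f"unknown region code: {self.region!r}")
        if self.species not in SPECIES_LABELS:
            raise ValueError(f"unknown species label: {self.species!r}")


FILTER_PRESETS = ("all", "fatal_only", "unprovoked_only", "white_only",
                  "white_tiger_bull")


def _years_consecutive(years: np.ndarray) -> bool:
    return bool(np.all(np.diff(years) == 1)) if years.size > 1 else True


@dataclass(frozen=True)
class CountSeries:
    """Yearly bite counts for one region over consecutive years."""

    region: str
    years: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "years", np.asarray(self.years, dtype=int))
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=float))
        if self.years.shape != self.counts.shape:
            raise AlignmentError("years and counts differ in length")
        if not _years_consecutive(self.years):
            raise ValidationError("years must be strictly consecutive")
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")


@dataclass(frozen=True)
class PopulationSeries:
    """Yearly human population for one region (observed + projected)."""

    region: str
    years: np.ndarray
    population: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "years", np.asarray(self.years, dtype=int))
        object.__setattr__(
            self, "population", np.asarray(self.population, dtype=float))
        if self.years.shape != self.population.shape:
            raise AlignmentError("years and population differ in length")
        if not _years_consecutive(self.years):
            raise ValidationError("years must be strictly consecutive")
        if np.any(self.population <= 0):
            raise ValidationError("population must be positive everywhere")

    def slice(self, years: Sequence[int]) -> "PopulationSeries":
        """Restrict to the given consecutive years; error if not covered."""
        years = np.asarray(years, dtype=int)
        if years[0] < self.years[0] or years[-1] > self.years[-1]:
            raise AlignmentError(
                f"population for {self.region} covers "
                f"{self.years[0]}–{self.years[-1]}, requested "
                f"{years[0]}–{years[-1]}")
        i0 = int(years[0] - self.years[0])
        return PopulationSeries(self.region, years,
                                self.population[i0:i0 + len(years)])


@dataclass(frozen=True)
class RateSeries:
    """Yearly bites person⁻¹ year⁻¹ for one region."""

    region: str
    years: np.ndarray
    rate: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "years", np.asarray(self.years, dtype=int))
        object.__setattr__(self, "rate", np.asarray(self.rate, dtype=float))
        if self.years.shape != self.rate.shape:
            raise AlignmentError("years and rate differ in length")
        if np.any(self.rate < 0):
            raise ValidationError("rates must be non-negative")


@dataclass(frozen=True)
class ScaledRateSeries:
    """Dimensionless rate series with its stored RMS divisor.

    ``scaled * scale_factor`` recovers the rate series exactly;
    ``scale_factor`` is ``sqrt(sum(rate**2) / (n - 1))``.
    """

    region: str
    years: np.ndarray
    scaled: np.ndarray
    scale_factor: float

    def __post_init__(self):
        object.__setattr__(self, "years", np.asarray(self.years, dtype=int))
        object.__setattr__(self, "scaled", np.asarray(self.scaled, dtype=float))
        if self.scale_factor <= 0:
            raise ValidationError("scale_factor must be positive")


# ---------------------------------------------------------------------------
# Reading and writing


def read_incidents(path, window=DEFAULT_WINDOW) -> list[IncidentRecord]:
    """Read an incident table (columns year,region,species,fatal,provoked).

    Every row is parsed or rejected; if any row fails, a
    :class:`~sharkcast.errors.ValidationError` carrying the full
    row-indexed error report is raised.  Species free text is normalized
    through :data:`SPECIES_ALIASES`.  ``window=None`` disables the
    study-window check on years.
    """
    try:
        frame = pd.read_csv(path, dtype=str)
    except Exception as exc:  # pragma: no cover - passthrough of IO errors
        raise FormatError(f"cannot read incident CSV {path}: {exc}") from exc
    frame.columns = [c.strip().lower() for c in frame.columns]
    required = ["year", "region", "species", "fatal", "provoked"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(
            f"incident CSV missing column(s): {', '.join(missing)}")

    records: list[IncidentRecord] = []
    row_errors: list[tuple[int, str]] = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        try:
            records.append(parse_incident_row(
                year=getattr(row, "year"), region=getattr(row, "region"),
                species=getattr(row, "species"), fatal=getattr(row, "fatal"),
                provoked=getattr(row, "provoked"), window=window))
        except (ValueError, TypeError) as exc:
            row_errors.append((i, str(exc)))
    if row_errors:
        head = "; ".join(f"row {r}: {m}" for r, m in row_errors[:5])
        raise ValidationError(
            f"{len(row_errors)} invalid incident row(s): {head}",
            row_errors=row_errors)
    return records


def parse_incident_row(year, region, species, fatal, provoked,
                       window=DEFAULT_WINDOW) -> IncidentRecord:
    """Validate and normalize one raw incident row."""
    year = int(str(year).strip())
    if window is not None and not (window[0] <= year <= window[1]):
        raise ValueError(f"year {year} outside study window "
                         f"{window[0]}–{window[1]}")
    region = str(region).strip()
    region_norm = region.upper() if region.upper() in REGION_CODES else (
        UNKNOWN_REGION if region.lower() == UNKNOWN_REGION else region)
    species_raw = str(species).strip().lower()
    species_norm = SPECIES_ALIASES.get(species_raw, species_raw)
    return IncidentRecord(year=year, region=region_norm, species=species_norm,
                          fatal=_parse_bool(fatal), provoked=_parse_bool(provoked))


def write_incidents(records: Iterable[IncidentRecord], path) -> None:
    """Write incidents as the canonical 5-column CSV."""
    frame = pd.DataFrame(
        [(r.year, r.region, r.species, int(r.fatal), int(r.provoked))
         for r in records],
        columns=["year", "region", "species", "fatal", "provoked"])
    frame.to_csv(path, index=False)


def read_population(path) -> dict[str, PopulationSeries]:
    """Read a long population table (columns region,year,population)."""
    frame = pd.read_csv(path)
    frame.columns = [c.strip().lower() for c in frame.columns]
    missing = [c for c in ("region", "year", "population")
               if c not in frame.columns]
    if missing:
        raise FormatError(
            f"population CSV missing column(s): {', '.join(missing)}")
    out = {}
    for region, grp in frame.groupby("region", sort=False):
        grp = grp.sort_values("year")
        out[str(region)] = PopulationSeries(
            str(region), grp["year"].to_numpy(), grp["population"].to_numpy())
    return out


def write_population(series: dict[str, PopulationSeries], path) -> None:
    frames = [
        pd.DataFrame({"region": s.region, "year": s.years,
                      "population": s.population})
        for s in series.values()
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Filtering and series construction


def filter_incidents(records: Sequence[IncidentRecord],
                     preset: str) -> list[IncidentRecord]:
    """Apply one of the closed filter presets.

    ``all`` keeps everything; ``fatal_only`` keeps fatal incidents;
    ``unprovoked_only`` keeps incidents not classed as provoked;
    ``white_only`` keeps white-shark incidents; ``white_tiger_bull`` keeps
    the three species most often responsible for bites.
    """
    if preset not in FILTER_PRESETS:
        raise ValidationError(
            f"unknown filter preset {preset!r}; expected one of "
            f"{', '.join(FILTER_PRESETS)}")
    if preset == "all":
        return list(records)
    if preset == "fatal_only":
        return [r for r in records if r.fatal]
    if preset == "unprovoked_only":
        return [r for r in records if not r.provoked]
    if preset == "white_only":
        return [r for r in records if r.species == "white"]
    return [r for r in records if r.species in ("white", "tiger", "bull")]


def build_count_series(records: Sequence[IncidentRecord], region: str,
                       years: Sequence[int]) -> CountSeries:
    """Count incidents per year for a region over a consecutive window.

    ``region="AUS"`` aggregates every record, including those with an
    unknown state; a state code counts only its own records.
    """
    years = np.asarray(years, dtype=int)
    if not _years_consecutive(years):
        raise ValidationError("years must be strictly consecutive")
    if region != AUS and region not in REGION_CODES:
        raise ValidationError(f"unknown region code: {region!r}")
    counts = np.zeros(len(years), dtype=float)
    y0, y1 = int(years[0]), int(years[-1])
    for r in records:
        if region != AUS and r.region != region:
            continue
        if y0 <= r.year <= y1:
            counts[r.year - y0] += 1
    return CountSeries(region, years, counts)


def to_per_capita(counts: CountSeries, pop: PopulationSeries) -> RateSeries:
    """Convert yearly counts to bites person⁻¹ year⁻¹."""
    if counts.region != pop.region:
        raise AlignmentError(
            f"region mismatch: counts {counts.region}, population {pop.region}")
    if not np.array_equal(counts.years, pop.years):
        pop = pop.slice(counts.years)
    return RateSeries(counts.region, counts.years,
                      counts.counts / pop.population)


def rms_scale(rates: RateSeries) -> ScaledRateSeries:
    """Divide a rate series by its root mean square (n−1 denominator)."""
    n = len(rates.rate)
    if n < 2:
        raise DegenerateSeriesError("need at least 2 observations to scale")
    if not np.any(rates.rate > 0):
        raise DegenerateSeriesError("all-zero rate series cannot be scaled")
    factor = float(np.sqrt(np.sum(rates.rate ** 2) / (n - 1)))
    if factor == 0.0:   # squared rates underflowed
        raise DegenerateSeriesError(
            "rate series too close to zero to scale in double precision")
    return ScaledRateSeries(rates.region, rates.years,
                            rates.rate / factor, factor)


def unscale(scaled: ScaledRateSeries) -> RateSeries:
    """Exact inverse of :func:`rms_scale` via the stored factor."""
    return RateSeries(scaled.region, scaled.years,
                      scaled.scaled * scaled.scale_factor)
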