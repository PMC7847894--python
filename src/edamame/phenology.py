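"""Phenology date arithmetic and thermal-unit accumulation.

Soybean development is tracked by calendar stages: planting, emergence
(Ve, cotyledons above the soil), first flower (R1) and harvest.  Dates
are handled as 1-based day-of-year (DOY) within one season.

Thermal time is accumulated as growing degree days (GDD): the sum over
days of ``max(0, (Tmax + Tmin)/2 - Tbase)`` with a base temperature of
7 °C, below which soybean growth and development stop.  Intervals are
half-open ``[start, end)`` so that interval sums are exactly additive:
GDD(Ve→R1) + GDD(R1→harvest) = GDD(Ve→harvest).

:func:`derive_features` produces the twelve predictor variables used
to screen drivers of harvest quality: the four stage DOYs, squared
planting and harvest DOYs, the three stage-interval day counts and the
three stage-interval GDD sums.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

__all__ = [
    "PhenologyError",
    "PhenoDates",
    "WeatherSeries",
    "PhenoFeatures",
    "FEATURE_NAMES",
    "SOYBEAN_BASE_TEMP_C",
    "gdd",
    "derive_features",
]

#: Base temperature (°C) below which soybean development stops.
SOYBEAN_BASE_TEMP_C = 7.0

WEATHER_COLUMNS = ("year", "doy", "tmin_C", "tmax_C")


class PhenologyError(ValueError):
    """Invalid dates or weather coverage."""


@dataclass(frozen=True)
class PhenoDates:
    """Stage dates for one plot, as day-of-year within one season."""

    planting_doy: int
    ve_doy: int
    r1_doy: int
    harvest_doy: int
    year: int = 0

    def __post_init__(self) -> None:
        seq = (self.planting_doy, self.ve_doy, self.r1_doy, self.harvest_doy)
        if not all(a < b for a, b in zip(seq, seq[1:])):
            raise PhenologyError(
                "stage dates must satisfy planting < Ve < R1 < harvest, got "
                f"planting={self.planting_doy}, ve={self.ve_doy}, "
                f"r1={self.r1_doy}, harvest={self.harvest_doy}"
            )


class WeatherSeries:
    """Daily Tmin/Tmax series for one site-year (or several years).

    Wraps a DataFrame with columns ``year, doy, tmin_C, tmax_C``.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in WEATHER_COLUMNS if c not in frame.columns]
        if missing:
            raise PhenologyError(f"weather series missing columns: {missing}")
        frame = frame.loc[:, list(WEATHER_COLUMNS)].sort_values(["year", "doy"])
        frame = frame.reset_index(drop=True)
        if (frame["tmin_C"] > frame["tmax_C"]).any():
            bad = frame.index[frame["tmin_C"] > frame["tmax_C"]].tolist()
            raise PhenologyError(f"tmin_C > tmax_C at rows {bad[:5]}")
        if frame.duplicated(["year", "doy"]).any():
            raise PhenologyError("duplicate (year, doy) rows in weather series")
        self.frame = frame

    @classmethod
    def from_csv(cls, path) -> "WeatherSeries":
        return cls(pd.read_csv(path))

    def years(self) -> list[int]:
        return sorted(self.frame["year"].unique().tolist())

    def _one_year(self, year: int | None) -> pd.DataFrame:
        if year is None:
            ys = self.years()
            if len(ys) != 1:
                raise PhenologyError(
                    f"weather spans years {ys}; specify which year to use"
                )
            year = ys[0]
        sub = self.frame[self.frame["year"] == year]
        if sub.empty:
            raise PhenologyError(f"no weather data for year {year}")
        return sub


def gdd(
    weather: WeatherSeries,
    start_doy: int,
    end_doy: int,
    base_C: float = SOYBEAN_BASE_TEMP_C,
    year: int | None = None,
) -> float:
    """Growing degree days accumulated over the half-open interval
    ``[start_doy, end_doy)``.

    Daily contribution is ``max(0, (tmax + tmin)/2 - base_C)``; the end
    day itself contributes nothing, which makes adjacent intervals sum
    exactly.
    """
    if not start_doy < end_doy:
        raise PhenologyError(
            f"need start_doy < end_doy, got [{start_doy}, {end_doy})"
        )
    sub = weather._one_year(year)
    window = sub[(sub["doy"] >= start_doy) & (sub["doy"] < end_doy)]
    missing = sorted(set(range(start_doy, end_doy)) - set(window["doy"]))
    if missing:
        raise PhenologyError(
            f"weather gaps in [{start_doy}, {end_doy}): missing DOYs {missing[:10]}"
            + (" ..." if len(missing) > 10 else "")
        )
    tmean = (window["tmin_C"].to_numpy() + window["tmax_C"].to_numpy()) / 2.0
    return float(np.clip(tmean - base_C, 0.0, None).sum())


@dataclass(frozen=True)
class PhenoFeatures:
    """The twelve phenological/thermal predictors for one plot."""

    planting_doy: int
    planting_doy_sq: int
    ve_doy: int
    r1_doy: int
    harvest_doy: int
    harvest_doy_sq: int
    days_ve_r1: int
    days_r1_harvest: int
    days_ve_harvest: int
    gdd_ve_r1: float
    gdd_r1_harvest: float
    gdd_ve_harvest: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


FEATURE_NAMES: tuple[str, ...] = tuple(f.name for f in fields(PhenoFeatures))


def derive_features(
    dates: PhenoDates,
    weather: WeatherSeries,
    base_C: float = SOYBEAN_BASE_TEMP_C,
) -> PhenoFeatures:
    """All twelve predictors for one plot.

    Interval day counts are plain DOY differences; GDD sums use the
    half-open convention of :func:`gdd`, so the day-count and GDD
    interval decompositions are both exactly additive.
    """
    year = dates.year if dates.year else None
    g_ve_r1 = gdd(weather, dates.ve_doy, dates.r1_doy, base_C, year)
    g_r1_h = gdd(weather, dates.r1_doy, dates.harvest_doy, base_C, year)
    return PhenoFeatures(
        planting_doy=dates.planting_doy,
        planting_doy_sq=dates.planting_doy**2,
        ve_doy=dates.ve_doy,
        r1_doy=dates.r1_doy,
        harvest_doy=dates.harvest_doy,
        harvest_doy_sq=dates.harvest_doy**2,
        days_ve_r1=dates.r1_doy - dates.ve_doy,
        days_r1_harvest=dates.harvest_doy - dates.r1_doy,
        days_ve_harvest=dates.harvest_doy - dates.ve_doy,
        gdd_ve_r1=g_ve_r1,
        gdd_r1_harvest=g_r1_h,
        gdd_ve_harvest=g_ve_r1 + g_r1_h,
    )
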