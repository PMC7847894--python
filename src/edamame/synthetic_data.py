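"""Synthetic split-split-plot edamame trials with known ground truth.

Emulates a multi-environment staggered-planting trial: 2 years x 2
locations (environments), 3 planting dates (whole plot), 3 cultivars
of contrasting maturity (split plot; an indeterminate MG3 and
determinate MG5/MG6), sequential harvests every ~5 days from late seed
fill (R5.8) to pod yellowing (R7) nested within planting x cultivar
(split-split plot), and 3 blocks.

Generated per plot x harvest: hundred-pod weight following a logistic
rise to a plateau (with an optional post-plateau decline for the early
cultivar), and pod hue fading exponentially from just under 120 deg
toward 90 deg as pods yellow, faster for later plantings.  Raw
colorimeter a*/b* readings are back-solved from the hue trajectory
(b* drawn in a typical green-pod range, a* = -tan(hue - 90) * b*), so
the generator and the colorimetry module are exactly self-consistent.

Phenology is thermal-time driven: emergence 5-8 days after planting,
first flower (R1) when simulated GDD (base 7 deg C) reaches a cultivar
requirement that shrinks with later planting (short-day acceleration),
and an R5.8->R7 span that also shrinks with later planting, so late
plantings reach R7 faster and yield fewer harvests.

Every true parameter is recorded in a ground-truth ledger so that
downstream estimators can be tested for recovery.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .phenology import SOYBEAN_BASE_TEMP_C, WeatherSeries

__all__ = [
    "CultivarProfile",
    "TrialConfig",
    "SimulatedTrial",
    "DEFAULT_CULTIVARS",
    "simulate_weather",
    "simulate_trial",
    "simulate_color_readings",
    "simulate_quadratic_records",
    "write_trial_csvs",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CultivarProfile:
    """Ground-truth growth and trait parameters for one cultivar.

    ``gdd_ve_to_r1`` is the thermal-time requirement (deg C day, base
    7 deg C) from emergence to first flower at the earliest planting;
    ``photoperiod_accel`` removes that many deg C day per day of later
    planting (short days accelerate flowering).  The hundred-pod-weight
    curve is logistic in days since R5.8 with optional linear decline
    after ``hpw_decline_onset_day``; hue decays exponentially from
    ``hue_init_deg`` toward 90 deg with rate ``hue_decay`` per day,
    increased by ``hue_decay_per_delay_day`` per day of later planting.
    """

    name: str
    maturity_group: float
    determinate: bool
    gdd_ve_to_r1: float
    photoperiod_accel: float
    days_r1_to_r58: float
    days_r58_to_r7: float
    r7_shrink_per_delay_day: float
    hpw_asymptote_g: float
    hpw_midpoint_day: float
    hpw_rate: float
    hpw_decline_onset_day: float = float("inf")
    hpw_decline_g_per_day: float = 0.0
    hue_init_deg: float = 117.5
    hue_decay: float = 0.012
    hue_decay_per_delay_day: float = 0.0004

    def __post_init__(self) -> None:
        if not self.hpw_asymptote_g > 0:
            raise ValueError("hpw_asymptote_g must be positive")
        if not self.hue_decay > 0:
            raise ValueError("hue_decay must be positive")
        if not 90.0 < self.hue_init_deg < 120.0:
            raise ValueError("hue_init_deg must lie in (90, 120)")

    def hpw_mean(self, t: float) -> float:
        """Expected hundred-pod weight t days after R5.8."""
        w = self.hpw_asymptote_g / (
            1.0 + np.exp(-self.hpw_rate * (t - self.hpw_midpoint_day))
        )
        if t > self.hpw_decline_onset_day:
            w -= self.hpw_decline_g_per_day * (t - self.hpw_decline_onset_day)
        return float(max(w, 1.0))

    def hue_mean(self, t: float, planting_delay_days: float) -> float:
        """Expected hue angle t days after R5.8."""
        k = self.hue_decay + self.hue_decay_per_delay_day * planting_delay_days
        return 90.0 + (self.hue_init_deg - 90.0) * float(np.exp(-k * t))


#: Three cultivars of contrasting maturity mirroring a staggered-harvest
#: trial: an early indeterminate MG3 whose pod weight declines with very
#: late harvest, and determinate MG5/MG6 cultivars (the MG6 has darker
#: pods, hence a lower initial hue).
DEFAULT_CULTIVARS: tuple[CultivarProfile, ...] = (
    CultivarProfile(
        name="8080", maturity_group=3, determinate=False,
        gdd_ve_to_r1=450.0, photoperiod_accel=1.2,
        days_r1_to_r58=30.0, days_r58_to_r7=36.0, r7_shrink_per_delay_day=0.25,
        hpw_asymptote_g=32.0, hpw_midpoint_day=4.0, hpw_rate=0.30,
        hpw_decline_onset_day=25.0, hpw_decline_g_per_day=0.4,
        hue_init_deg=117.5, hue_decay=0.012, hue_decay_per_delay_day=0.0004,
    ),
    CultivarProfile(
        name="R08-4002", maturity_group=5, determinate=True,
        gdd_ve_to_r1=600.0, photoperiod_accel=1.5,
        days_r1_to_r58=33.0, days_r58_to_r7=30.0, r7_shrink_per_delay_day=0.22,
        hpw_asymptote_g=30.0, hpw_midpoint_day=4.0, hpw_rate=0.30,
        hue_init_deg=117.0, hue_decay=0.014, hue_decay_per_delay_day=0.0004,
    ),
    CultivarProfile(
        name="R09-345", maturity_group=6, determinate=True,
        gdd_ve_to_r1=700.0, photoperiod_accel=1.8,
        days_r1_to_r58=35.0, days_r58_to_r7=32.0, r7_shrink_per_delay_day=0.22,
        hpw_asymptote_g=26.0, hpw_midpoint_day=5.0, hpw_rate=0.28,
        hue_init_deg=113.0, hue_decay=0.013, hue_decay_per_delay_day=0.0005,
    ),
)


@dataclass(frozen=True)
class TrialConfig:
    """Design and noise settings for one simulated trial."""

    years: tuple[int, ...] = (2014, 2015)
    locations: tuple[str, ...] = ("Fayetteville", "Kibler")
    n_blocks: int = 3
    planting_doys: tuple[int, ...] = (135, 166, 196)  # mid-May/June/July
    harvest_interval_days: int = 5
    max_harvests: int = 8
    hpw_noise_sd: float = 2.0
    hue_noise_sd: float = 1.0
    # weather model: sinusoidal seasonal mean with AR(1) daily noise
    weather_mean_C: float = 15.5
    weather_amplitude_C: float = 11.5
    weather_peak_doy: int = 197
    weather_ar1: float = 0.7
    weather_noise_sd: float = 2.5
    diurnal_range_mean_C: float = 10.0
    diurnal_range_sd_C: float = 1.5

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.max_harvests < 1:
            raise ValueError("counts must be >= 1")
        if self.harvest_interval_days < 1:
            raise ValueError("harvest_interval_days must be >= 1")
        if list(self.planting_doys) != sorted(set(self.planting_doys)):
            raise ValueError("planting_doys must be strictly increasing")

    def environments(self) -> list[tuple[int, str]]:
        return [(y, loc) for y in self.years for loc in self.locations]


def _env_label(year: int, location: str) -> str:
    return f"{year}_{location}"


def simulate_weather(
    config: TrialConfig | None = None, seed: int = 0
) -> dict[str, WeatherSeries]:
    """Daily Tmin/Tmax for each environment, full calendar year.

    Mean temperature follows a sinusoid peaking in midsummer, with
    AR(1) day-to-day noise; Tmax - Tmin is a sampled positive diurnal
    range.  Environments get independent, seed-derived substreams, so
    the same seed always reproduces the same series.
    """
    config = config or TrialConfig()
    out: dict[str, WeatherSeries] = {}
    for i, (year, loc) in enumerate(config.environments()):
        rng = np.random.default_rng([seed, i])
        doy = np.arange(1, 366)
        seasonal = config.weather_mean_C + config.weather_amplitude_C * np.cos(
            2.0 * np.pi * (doy - config.weather_peak_doy) / 365.0
        )
        seasonal = seasonal + (0.8 if loc == config.locations[-1] else 0.0)
        noise = np.empty(len(doy))
        eps = rng.normal(0.0, config.weather_noise_sd, len(doy))
        noise[0] = eps[0]
        for t in range(1, len(doy)):
            noise[t] = config.weather_ar1 * noise[t - 1] + eps[t]
        tmean = seasonal + noise
        half_range = np.maximum(
            rng.normal(config.diurnal_range_mean_C, config.diurnal_range_sd_C,
                       len(doy)),
            1.0,
        ) / 2.0
        frame = pd.DataFrame(
            {
                "year": year,
                "doy": doy,
                "tmin_C": np.round(tmean - half_range, 3),
                "tmax_C": np.round(tmean + half_range, 3),
            }
        )
        out[_env_label(year, loc)] = WeatherSeries(frame)
    return out


@dataclass
class SimulatedTrial:
    """A generated trial: plot records, per-environment weather, and
    the ground-truth parameter ledger."""

    records: pd.DataFrame
    weather: dict[str, WeatherSeries]
    truth: dict


def _doy_of_gdd(weather: WeatherSeries, year: int, start_doy: int,
                requirement: float, base_C: float) -> int:
    """First DOY at which cumulative GDD from start_doy reaches the
    requirement (half-open daily accumulation)."""
    sub = weather._one_year(year)
    sub = sub[sub["doy"] >= start_doy]
    tmean = (sub["tmin_C"].to_numpy() + sub["tmax_C"].to_numpy()) / 2.0
    cum = np.cumsum(np.clip(tmean - base_C, 0.0, None))
    idx = np.searchsorted(cum, requirement)
    if idx >= len(cum):
        raise ValueError(
            f"weather year {year} too short to accumulate {requirement} GDD "
            f"from DOY {start_doy}"
        )
    return int(sub["doy"].to_numpy()[idx]) + 1


def simulate_trial(
    config: TrialConfig | None = None,
    cultivars: tuple[CultivarProfile, ...] = DEFAULT_CULTIVARS,
    seed: int = 0,
) -> SimulatedTrial:
    """Generate a complete trial ready for scoring and model fitting.

    Returns plot x harvest records (design factors, stage DOYs, HPW and
    raw a*/b* readings), the weather series used, and a ground-truth
    ledger holding every generating parameter and the realised stage
    dates per environment x planting x cultivar.
    """
    config = config or TrialConfig()
    weather = simulate_weather(config, seed)
    rng = np.random.default_rng([seed, 10_007])
    first_pd = min(config.planting_doys)

    rows = []
    pheno_truth: dict[str, dict] = {}
    for year, loc in config.environments():
        env = _env_label(year, loc)
        wx = weather[env]
        pheno_truth[env] = {}
        for pd_doy in config.planting_doys:
            delay = pd_doy - first_pd
            for cult in cultivars:
                ve = int(pd_doy + rng.integers(5, 9))
                req = max(cult.gdd_ve_to_r1 - cult.photoperiod_accel * delay,
                          150.0)
                r1 = _doy_of_gdd(wx, year, ve, req, SOYBEAN_BASE_TEMP_C)
                r58 = int(round(r1 + cult.days_r1_to_r58))
                span = cult.days_r58_to_r7 - cult.r7_shrink_per_delay_day * delay
                r7 = int(round(r58 + span))
                harvests = [
                    r58 + i * config.harvest_interval_days
                    for i in range(config.max_harvests)
                    if r58 + i * config.harvest_interval_days <= r7
                ]
                pheno_truth[env][f"PD{pd_doy}|{cult.name}"] = {
                    "ve_doy": ve, "r1_doy": r1, "r58_doy": r58, "r7_doy": r7,
                    "n_harvests": len(harvests),
                }
                if not harvests:
                    warnings.warn(
                        f"{env} PD{pd_doy} {cult.name}: R7 precedes R5.8; "
                        "no harvests generated",
                        stacklevel=2,
                    )
                    continue
                for block in range(1, config.n_blocks + 1):
                    for h_num, hd in enumerate(harvests, start=1):
                        t = hd - r58
                        hpw = cult.hpw_mean(t) + rng.normal(
                            0.0, config.hpw_noise_sd
                        ) if config.hpw_noise_sd > 0 else cult.hpw_mean(t)
                        hpw = max(hpw, 1.0)
                        hue = cult.hue_mean(t, delay)
                        if config.hue_noise_sd > 0:
                            hue += rng.normal(0.0, config.hue_noise_sd)
                        hue = float(np.clip(hue, 90.5, 119.5))
                        igc = float(np.tan(np.radians(hue - 90.0)))
                        b_star = float(rng.uniform(28.0, 32.0))
                        a_star = -igc * b_star
                        rows.append(
                            {
                                "plot_id": f"{env}_PD{pd_doy}_{cult.name}"
                                           f"_B{block}_H{h_num}",
                                "environment": env,
                                "year": year,
                                "location": loc,
                                "block": f"B{block}",
                                "cultivar": cult.name,
                                "planting_doy": pd_doy,
                                "ve_doy": ve,
                                "r1_doy": r1,
                                "r58_doy": r58,
                                "r7_doy": r7,
                                "harvest_number": h_num,
                                "harvest_doy": hd,
                                "hpw_g": float(hpw),
                                "a_star": a_star,
                                "b_star": b_star,
                            }
                        )
    records = pd.DataFrame(rows)
    truth = {
        "seed": seed,
        "config": dataclasses.asdict(config),
        "cultivars": {c.name: dataclasses.asdict(c) for c in cultivars},
        "phenology": pheno_truth,
    }
    logger.info("simulated trial: %d plot-harvest records", len(records))
    return SimulatedTrial(records=records, weather=weather, truth=truth)


def simulate_color_readings(
    n: int = 1000,
    igc_range: tuple[float, float] = (0.2, 0.6),
    b_range: tuple[float, float] = (25.0, 35.0),
    noise_sd: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Noisy colorimeter readings spanning the realistic green-pod range.

    b* is uniform on ``b_range``; a* is set so the noiseless -a*/b*
    ratio is uniform on ``igc_range``; independent Gaussian noise of sd
    ``noise_sd`` is then added to each channel, emulating instrument
    repeatability error.
    """
    rng = np.random.default_rng(seed)
    b_true = rng.uniform(*b_range, n)
    igc_true = rng.uniform(*igc_range, n)
    a_true = -igc_true * b_true
    return pd.DataFrame(
        {
            "sample_id": [f"S{i:04d}" for i in range(n)],
            "a_star": a_true + rng.normal(0.0, noise_sd, n),
            "b_star": b_true + rng.normal(0.0, noise_sd, n),
        }
    )


def simulate_quadratic_records(
    n: int,
    intercept: float,
    beta_pd: float,
    beta_pd2: float,
    beta_hd: float,
    beta_hd2: float,
    pd_range: tuple[float, float] = (135.0, 196.0),
    hd_range: tuple[float, float] = (210.0, 280.0),
    noise_sd: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Plot records whose EHQI comes from a known quadratic surface.

    Used for parameter-recovery studies: planting and harvest DOYs are
    uniform over their ranges and Gaussian noise of sd ``noise_sd`` is
    added to the deterministic surface value.
    """
    rng = np.random.default_rng(seed)
    pd_doy = rng.uniform(*pd_range, n)
    hd_doy = rng.uniform(*hd_range, n)
    ehqi = (
        intercept
        + beta_pd * pd_doy
        + beta_pd2 * pd_doy**2
        + beta_hd * hd_doy
        + beta_hd2 * hd_doy**2
        + rng.normal(0.0, noise_sd, n)
    )
    return pd.DataFrame(
        {"planting_doy": pd_doy, "harvest_doy": hd_doy, "ehqi": ehqi}
    )


def write_trial_csvs(trial: SimulatedTrial, out_dir) -> dict[str, Path]:
    """Write weather.csv, quality.csv, colors.csv and truth.json.

    Output is deterministic: identical trials produce byte-identical
    files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    wx = pd.concat(
        [ws.frame.assign(environment=env) for env, ws in trial.weather.items()],
        ignore_index=True,
    )
    paths["weather"] = out / "weather.csv"
    wx.to_csv(paths["weather"], index=False)
    paths["quality"] = out / "quality.csv"
    trial.records.to_csv(paths["quality"], index=False)
    colors = trial.records[["plot_id", "a_star", "b_star"]].rename(
        columns={"plot_id": "sample_id"}
    )
    paths["colors"] = out / "colors.csv"
    colors.to_csv(paths["colors"], index=False)
    paths["truth"] = out / "truth.json"
    paths["truth"].write_text(json.dumps(trial.truth, indent=2, sort_keys=True))
    return paths
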