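"""CSV/JSON interchange and schema validation.

Plot-level trial tables and weather series travel as headed CSV;
fitted surface models travel as JSON.  Schema violations are reported
with the offending column or row so that malformed field exports fail
loudly at the pipeline boundary.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd

from .phenology import WeatherSeries
from .response_surface import SurfaceModel, HarvestWindow

__all__ = [
    "SchemaError",
    "QUALITY_COLUMNS",
    "COLOR_COLUMNS",
    "read_quality_csv",
    "read_colors_csv",
    "read_weather_csv",
    "write_model_json",
    "read_model_json",
    "window_to_dict",
]

QUALITY_COLUMNS = (
    "plot_id", "cultivar", "environment", "block",
    "planting_doy", "harvest_doy", "hpw_g", "a_star", "b_star",
)
COLOR_COLUMNS = ("sample_id", "a_star", "b_star")
WEATHER_COLUMNS = ("year", "doy", "tmin_C", "tmax_C")


class SchemaError(ValueError):
    """A CSV does not match its expected schema."""


def _read_checked(path, required: tuple[str, ...], what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{what} file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} CSV {path} missing columns: {missing}")
    return df


def read_quality_csv(path) -> pd.DataFrame:
    """Plot-level quality-input table; numeric columns are validated
    row-wise with 1-based row numbers in error messages."""
    df = _read_checked(path, QUALITY_COLUMNS, "quality")
    for col in ("planting_doy", "harvest_doy", "hpw_g", "a_star", "b_star"):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise SchemaError(
                f"quality CSV column {col!r}: non-numeric values at rows "
                f"{[int(i) + 2 for i in bad[:5]]}"  # header is row 1
            )
    return df


def read_colors_csv(path) -> pd.DataFrame:
    return _read_checked(path, COLOR_COLUMNS, "colors")


def read_weather_csv(path) -> dict[str, WeatherSeries] | WeatherSeries:
    """Weather CSV; an optional ``environment`` column splits the file
    into one series per environment."""
    df = _read_checked(path, WEATHER_COLUMNS, "weather")
    if "environment" in df.columns:
        return {
            env: WeatherSeries(sub.drop(columns="environment"))
            for env, sub in df.groupby("environment")
        }
    return WeatherSeries(df)


def write_model_json(model: SurfaceModel, path) -> None:
    d = dataclasses.asdict(model)
    Path(path).write_text(json.dumps(d, indent=2, sort_keys=True))


def read_model_json(path) -> SurfaceModel:
    d = json.loads(Path(path).read_text())
    d["included_terms"] = tuple(d["included_terms"])
    for key in ("pd_range", "hd_range"):
        if d.get(key) is not None:
            d[key] = tuple(d[key])
    return SurfaceModel(**d)


def window_to_dict(window: HarvestWindow) -> dict:
    return dataclasses.asdict(window)
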