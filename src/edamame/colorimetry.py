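"""CIELAB colorimetry for edamame pod color.

Pod color is measured with a bench colorimeter as CIELAB opponent
coordinates: a* (negative = green, positive = red) and b* (negative =
blue, positive = yellow).  Two derived traits summarise how green a pod
sample is:

* **IGC** (intensity of green color), the ratio ``-a*/b*``.  For green
  pods (a* < 0, b* > 0) larger IGC means a deeper green.
* **hue angle**, the angular position of the (a*, b*) vector in the
  color plane measured counter-clockwise from the +a* axis, in degrees
  on [0, 360).  Pure red, yellow, green and blue sit at 0°, 90°, 180°
  and 270°; green pods land in (90°, 180°), approaching 180° as they
  get greener.

The two traits are deterministically linked on the green-pod quadrant:
``hue = 90° + arctan(IGC)`` (in degrees), which is why they correlate
near-perfectly in trial data.

Colorimeters are calibrated against standard tiles (black glass, white,
and a green validation tile); :func:`validate_calibration` checks tile
readings against their reference coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ColorimetryError",
    "ColorReading",
    "ColorIndices",
    "CalibrationStandard",
    "CalibrationCheck",
    "CalibrationReport",
    "WHITE_TILE",
    "GREEN_TILE",
    "BLACK_TILE",
    "compute_igc",
    "compute_hue",
    "igc_from_ab",
    "hue_from_ab",
    "indices_for",
    "validate_calibration",
]


class ColorimetryError(ValueError):
    """Invalid colorimeter reading or calibration configuration."""


@dataclass(frozen=True)
class ColorReading:
    """One colorimeter measurement of a pod sample (a*, b*)."""

    a_star: float
    b_star: float
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not (math.isfinite(self.a_star) and math.isfinite(self.b_star)):
            raise ColorimetryError(
                f"non-finite CIELAB coordinates for sample {self.sample_id!r}"
            )


@dataclass(frozen=True)
class ColorIndices:
    """Derived green-color traits for one reading."""

    igc: float
    hue_deg: float


@dataclass(frozen=True)
class CalibrationStandard:
    """Reference tile with expected (a*, b*) and an acceptance tolerance."""

    name: str
    a_star_ref: float
    b_star_ref: float
    tolerance: float = 0.5

    def __post_init__(self) -> None:
        if not self.tolerance > 0:
            raise ColorimetryError(
                f"calibration tolerance must be positive, got {self.tolerance}"
            )


# Standard tiles shipped with the instrument.  The white tile carries the
# manufacturer's (a*, b*) certificate; the green tile is used to validate
# a black/white calibration.
WHITE_TILE = CalibrationStandard("white", -0.93, 1.02)
GREEN_TILE = CalibrationStandard("green", -25.30, 13.71)
BLACK_TILE = CalibrationStandard("black", 0.0, 0.0)


def igc_from_ab(a_star, b_star):
    """Vectorised IGC = -a*/b*.  Raises if any b* is zero."""
    a = np.asarray(a_star, dtype=float)
    b = np.asarray(b_star, dtype=float)
    if np.any(b == 0):
        raise ColorimetryError("IGC undefined where b* = 0")
    return -a / b


def hue_from_ab(a_star, b_star):
    """Vectorised quadrant-correct hue angle in degrees on [0, 360)."""
    a = np.asarray(a_star, dtype=float)
    b = np.asarray(b_star, dtype=float)
    if np.any((a == 0) & (b == 0)):
        raise ColorimetryError("hue undefined at the achromatic point a* = b* = 0")
    return np.degrees(np.arctan2(b, a)) % 360.0


def compute_igc(reading: ColorReading) -> float:
    """Intensity of green color, ``-a*/b*``, for a single reading.

    Positive exactly when a* and b* have opposite signs; for green pods
    (a* < 0, b* > 0) larger values indicate a more intense green.
    """
    if reading.b_star == 0:
        raise ColorimetryError(
            f"IGC undefined for sample {reading.sample_id!r}: b* = 0"
        )
    return -reading.a_star / reading.b_star


def compute_hue(reading: ColorReading) -> float:
    """Hue angle in degrees on [0, 360) for a single reading."""
    if reading.a_star == 0 and reading.b_star == 0:
        raise ColorimetryError(
            f"hue undefined for sample {reading.sample_id!r}: a* = b* = 0"
        )
    return math.degrees(math.atan2(reading.b_star, reading.a_star)) % 360.0


def indices_for(reading: ColorReading) -> ColorIndices:
    """Both derived color traits for one reading."""
    return ColorIndices(igc=compute_igc(reading), hue_deg=compute_hue(reading))


@dataclass(frozen=True)
class CalibrationCheck:
    """Deviation of one tile reading from its standard."""

    sample_id: str
    standard: str
    a_dev: float
    b_dev: float
    tolerance: float
    passed: bool


@dataclass(frozen=True)
class CalibrationReport:
    """Per-tile deviations; overall pass iff every check passed."""

    checks: tuple[CalibrationCheck, ...]

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def failures(self) -> tuple[CalibrationCheck, ...]:
        return tuple(c for c in self.checks if not c.passed)


def validate_calibration(
    readings: Iterable[ColorReading],
    standards: Sequence[CalibrationStandard] = (BLACK_TILE, WHITE_TILE, GREEN_TILE),
) -> CalibrationReport:
    """Check tile readings against their reference coordinates.

    Each reading's ``sample_id`` must name one of the supplied standards;
    a reading fails if |a* − ref| or |b* − ref| exceeds the standard's
    tolerance.  An empty reading list yields a vacuously passing report.
    """
    table = {s.name: s for s in standards}
    checks = []
    for r in readings:
        std = table.get(r.sample_id)
        if std is None:
            raise ColorimetryError(
                f"reading labelled {r.sample_id!r} matches no calibration "
                f"standard (known: {sorted(table)})"
            )
        a_dev = abs(r.a_star - std.a_star_ref)
        b_dev = abs(r.b_star - std.b_star_ref)
        checks.append(
            CalibrationCheck(
                sample_id=r.sample_id,
                standard=std.name,
                a_dev=a_dev,
                b_dev=b_dev,
                tolerance=std.tolerance,
                passed=a_dev <= std.tolerance and b_dev <= std.tolerance,
            )
        )
    return CalibrationReport(checks=tuple(checks))
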