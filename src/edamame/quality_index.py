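"""The Edamame Harvest Quality Index (EHQI).

Edamame quality is driven by two harvest-time traits: pod size,
measured as hundred-pod weight (HPW, grams per 100 pods before
blanching), and green pod color, measured as hue angle and intensity
of green color (IGC).  EHQI folds them into a single score:

    EHQI = (HPW / HPWmax) / ((120 - hue) * (1 - IGC))

where HPWmax is the maximum HPW observed for the same cultivar,
planting date and environment (year x location) across its harvest
dates and blocks.  The weight ratio rewards large pods relative to the
cultivar's own potential in that trial; the color product in the
denominator shrinks toward zero as hue approaches the 120-degree
quality anchor and IGC approaches 1, so greener pods score higher.
Larger EHQI means better harvest quality, with values in (0, 1).

The raw formula is undefined (or explodes past 1) when hue >= 120 or
IGC >= 1; a clamp policy decides whether such rows are rejected with a
diagnostic (default) or clamped into (eps, 1 - eps), matching the
convention that the index lives strictly inside the unit interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .colorimetry import hue_from_ab, igc_from_ab

__all__ = [
    "QualityIndexError",
    "EHQI_EPS",
    "GROUP_KEY",
    "compute_hpw_max",
    "compute_ehqi",
    "score_dataset",
    "ScoreReport",
]

logger = logging.getLogger(__name__)

#: Clamp margin keeping EHQI strictly inside (0, 1).
EHQI_EPS = 1e-3

#: Grouping key for the per-combination HPW maximum.
GROUP_KEY = ("cultivar", "planting_doy", "environment")

_POLICIES = ("reject", "clamp")


class QualityIndexError(ValueError):
    """Invalid quality-index input (weights, color, groups, or policy)."""


def _check_policy(clamp_policy: str) -> None:
    if clamp_policy not in _POLICIES:
        raise QualityIndexError(
            f"unknown clamp policy {clamp_policy!r}; expected one of {_POLICIES}"
        )


def compute_hpw_max(records: pd.DataFrame) -> pd.Series:
    """Per-(cultivar, planting date, environment) maximum hundred-pod weight.

    The maximum is taken across harvest dates and blocks within each
    combination; it anchors the weight ratio in EHQI so that exactly one
    record per group attains ratio 1.
    """
    missing = [c for c in (*GROUP_KEY, "hpw_g") if c not in records.columns]
    if missing:
        raise QualityIndexError(f"records missing columns: {missing}")
    if records.empty:
        raise QualityIndexError("cannot compute HPW maxima from empty records")
    if (records["hpw_g"] <= 0).any():
        bad = records.index[records["hpw_g"] <= 0].tolist()
        raise QualityIndexError(f"non-positive hpw_g at rows {bad[:5]}")
    return records.groupby(list(GROUP_KEY))["hpw_g"].max()


def compute_ehqi(
    hpw_g: float,
    hpw_max_g: float,
    hue_deg: float,
    igc: float,
    clamp_policy: str = "reject",
) -> float:
    """EHQI for one record.

    Under the default ``reject`` policy a non-positive denominator
    (hue >= 120 or IGC >= 1) or a raw value outside (0, 1) raises
    :class:`QualityIndexError`; under ``clamp`` the result is clipped
    into ``(EHQI_EPS, 1 - EHQI_EPS)`` with a logged warning.
    """
    _check_policy(clamp_policy)
    if not hpw_g > 0:
        raise QualityIndexError(f"hpw_g must be positive, got {hpw_g}")
    if not hpw_max_g >= hpw_g:
        raise QualityIndexError(
            f"hpw_max_g ({hpw_max_g}) must be >= hpw_g ({hpw_g})"
        )
    denom = (120.0 - hue_deg) * (1.0 - igc)
    if denom <= 0:
        if clamp_policy == "reject":
            raise QualityIndexError(
                f"EHQI undefined: non-positive denominator "
                f"(hue={hue_deg:.3f} deg, igc={igc:.4f})"
            )
        logger.warning(
            "EHQI denominator non-positive (hue=%.3f, igc=%.4f); clamping to %g",
            hue_deg, igc, 1.0 - EHQI_EPS,
        )
        return 1.0 - EHQI_EPS
    raw = (hpw_g / hpw_max_g) / denom
    if clamp_policy == "clamp":
        if raw >= 1.0 - EHQI_EPS or raw <= EHQI_EPS:
            logger.warning("EHQI %.4f outside (0, 1); clamping", raw)
        return min(max(raw, EHQI_EPS), 1.0 - EHQI_EPS)
    if raw >= 1.0:
        raise QualityIndexError(
            f"EHQI {raw:.4f} >= 1 under reject policy "
            f"(hue={hue_deg:.3f}, igc={igc:.4f})"
        )
    return raw


@dataclass
class ScoreReport:
    """Accounting of a scoring pass: every input row is scored, clamped
    or dropped."""

    n_input: int = 0
    n_scored: int = 0
    n_clamped: int = 0
    n_dropped: int = 0
    dropped_rows: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_scored": self.n_scored,
            "n_clamped": self.n_clamped,
            "n_dropped": self.n_dropped,
            "dropped_rows": list(self.dropped_rows),
        }


def score_dataset(
    records: pd.DataFrame,
    hpw_table: pd.Series | None = None,
    clamp_policy: str = "reject",
) -> tuple[pd.DataFrame, ScoreReport]:
    """Populate ``igc``, ``hue_deg`` and ``ehqi`` for a plot-level table.

    ``records`` needs the grouping columns, ``hpw_g`` and either both
    color indices or raw ``a_star``/``b_star`` readings to derive them.
    ``hpw_table`` defaults to the per-group maxima of the data itself.
    Under the ``reject`` policy, rows with an invalid index are dropped
    and listed in the report rather than raising, so one bad reading
    does not abort a whole trial.
    """
    _check_policy(clamp_policy)
    df = records.copy()
    report = ScoreReport(n_input=len(df))

    if "igc" not in df.columns or "hue_deg" not in df.columns:
        for col in ("a_star", "b_star"):
            if col not in df.columns:
                raise QualityIndexError(
                    f"records need igc/hue_deg or a_star/b_star; missing {col!r}"
                )
        df["igc"] = igc_from_ab(df["a_star"], df["b_star"])
        df["hue_deg"] = hue_from_ab(df["a_star"], df["b_star"])

    key_cols = [*GROUP_KEY, "harvest_doy", "block"]
    if all(c in df.columns for c in key_cols) and df.duplicated(key_cols).any():
        logger.warning("duplicate (cultivar, environment, planting, harvest, "
                       "block) keys in records")

    if hpw_table is None:
        hpw_table = compute_hpw_max(df)

    keys = pd.MultiIndex.from_frame(df[list(GROUP_KEY)])
    missing = sorted(set(keys) - set(hpw_table.index))
    if missing:
        raise QualityIndexError(
            f"HPW-max table missing groups: {missing[:5]}"
            + (" ..." if len(missing) > 5 else "")
        )
    hpw_max = hpw_table.reindex(keys).to_numpy()

    if (df["hpw_g"] <= 0).any():
        raise QualityIndexError("non-positive hpw_g in records")

    denom = (120.0 - df["hue_deg"].to_numpy()) * (1.0 - df["igc"].to_numpy())
    ratio = df["hpw_g"].to_numpy() / hpw_max
    with pd.option_context("mode.chained_assignment", None):
        raw = pd.Series(ratio, index=df.index) / denom
    invalid = (denom <= 0) | (raw >= 1.0) | (raw <= 0.0)

    if clamp_policy == "reject":
        dropped = df.index[invalid]
        if len(dropped):
            logger.warning("dropping %d rows with invalid EHQI", len(dropped))
        report.dropped_rows = dropped.tolist()
        report.n_dropped = len(dropped)
        df = df.loc[~invalid]
        df["ehqi"] = raw.loc[~invalid]
    else:
        clamped = invalid | (raw >= 1.0 - EHQI_EPS) | (raw <= EHQI_EPS)
        report.n_clamped = int(clamped.sum())
        ehqi = raw.clip(EHQI_EPS, 1.0 - EHQI_EPS)
        ehqi[denom <= 0] = 1.0 - EHQI_EPS
        df["ehqi"] = ehqi
        if report.n_clamped:
            logger.warning("clamped %d rows into (%g, %g)",
                           report.n_clamped, EHQI_EPS, 1 - EHQI_EPS)
    report.n_scored = len(df)
    return df, report
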