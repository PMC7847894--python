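"""Quadratic planting x harvest response surfaces and harvest windows.

Within one cultivar, harvest quality (EHQI) is modelled as an ordinary
least-squares quadratic in planting and harvest day-of-year:

    EHQI = b0 + b1*PD + b2*PD^2 + b3*HD + b4*HD^2 + error

with no PD x HD interaction, so the harvest-date curvature is the same
at every planting date.  A negative harvest-date curvature (b4 < 0)
gives an interior quality peak at HD* = -b3 / (2*b4), and the set of
harvest days whose predicted quality stays within a tolerance ``t`` of
the peak is an interval symmetric about HD* with full width

    width = 2 * sqrt(t / |b4|)   [days],

the cultivar's *harvest window*: how long harvest can slip from the
optimum before predicted quality drops by more than ``t`` index units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .model_selection import stepwise_select

__all__ = [
    "ResponseSurfaceError",
    "SURFACE_TERMS",
    "SurfaceModel",
    "HarvestWindow",
    "fit_surface",
    "predict_surface",
    "find_peak",
    "harvest_window",
]

#: Candidate terms of the quadratic surface, in design order.
SURFACE_TERMS = ("planting_doy", "planting_doy_sq", "harvest_doy", "harvest_doy_sq")

_BETA_ATTR = {
    "planting_doy": "beta_pd",
    "planting_doy_sq": "beta_pd2",
    "harvest_doy": "beta_hd",
    "harvest_doy_sq": "beta_hd2",
}


class ResponseSurfaceError(ValueError):
    """Degenerate design or model without an interior maximum."""


@dataclass(frozen=True)
class SurfaceModel:
    """Fitted (or published) quadratic EHQI response surface.

    Terms excluded by selection carry coefficient 0 and are absent from
    ``included_terms``.
    """

    intercept: float
    beta_pd: float
    beta_pd2: float
    beta_hd: float
    beta_hd2: float
    included_terms: tuple[str, ...] = SURFACE_TERMS
    rmse: float | None = None
    adj_r2: float | None = None
    pd_range: tuple[float, float] | None = None
    hd_range: tuple[float, float] | None = None

    def coefficient(self, term: str) -> float:
        if term == "intercept":
            return self.intercept
        return getattr(self, _BETA_ATTR[term])

    def predict(self, planting_doy, harvest_doy):
        """Pointwise polynomial evaluation (broadcasts like numpy)."""
        pd_ = np.asarray(planting_doy, dtype=float)
        hd_ = np.asarray(harvest_doy, dtype=float)
        out = (
            self.intercept
            + self.beta_pd * pd_
            + self.beta_pd2 * pd_**2
            + self.beta_hd * hd_
            + self.beta_hd2 * hd_**2
        )
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class HarvestWindow:
    """Tolerance band around the quality peak along the harvest axis."""

    peak_harvest_doy: float
    peak_ehqi: float | None
    tolerance: float
    window_start_doy: float
    window_end_doy: float
    width_days: float
    width_days_rounded: int


def _check_rank(X: pd.DataFrame) -> None:
    A = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        involved = []
        for j, name in enumerate(X.columns):
            reduced = np.delete(A, j + 1, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                involved.append(name)
        raise ResponseSurfaceError(
            f"design is rank deficient; collinear terms: {involved or list(X.columns)}"
        )


def fit_surface(
    records: pd.DataFrame,
    selection: str = "full",
    entry_p: float = 0.15,
    stay_p: float = 0.15,
) -> SurfaceModel:
    """Fit the quadratic EHQI surface for one cultivar.

    ``selection="full"`` fits all four terms by OLS; ``"stepwise"``
    runs bidirectional stepwise selection (enter/stay p = 0.15, minimum
    AIC) over the four candidate terms, mirroring how trial analyses
    drop non-significant terms (e.g. a linear planting-date term).
    Requires at least 6 distinct (planting, harvest) support points.
    """
    for col in ("planting_doy", "harvest_doy", "ehqi"):
        if col not in records.columns:
            raise ResponseSurfaceError(f"records missing column {col!r}")
    support = records[["planting_doy", "harvest_doy"]].drop_duplicates()
    if len(support) < 6:
        raise ResponseSurfaceError(
            f"need >= 6 distinct (planting, harvest) support points, "
            f"got {len(support)}"
        )
    X = pd.DataFrame(
        {
            "planting_doy": records["planting_doy"].astype(float),
            "planting_doy_sq": records["planting_doy"].astype(float) ** 2,
            "harvest_doy": records["harvest_doy"].astype(float),
            "harvest_doy_sq": records["harvest_doy"].astype(float) ** 2,
        },
        index=records.index,
    )
    y = records["ehqi"].astype(float)
    _check_rank(X)

    if selection == "stepwise":
        result = stepwise_select(y, X, entry_p=entry_p, stay_p=stay_p)
        terms = tuple(t for t in SURFACE_TERMS if t in result.selected_terms)
    elif selection == "full":
        terms = SURFACE_TERMS
    else:
        raise ResponseSurfaceError(
            f"unknown selection {selection!r}; expected 'full' or 'stepwise'"
        )

    design = sm.add_constant(X[list(terms)], has_constant="add")
    fit = sm.OLS(y, design).fit()
    coefs = {t: 0.0 for t in SURFACE_TERMS}
    for t in terms:
        coefs[t] = float(fit.params[t])
    dof = max(len(y) - len(terms) - 1, 1)
    return SurfaceModel(
        intercept=float(fit.params["const"]),
        beta_pd=coefs["planting_doy"],
        beta_pd2=coefs["planting_doy_sq"],
        beta_hd=coefs["harvest_doy"],
        beta_hd2=coefs["harvest_doy_sq"],
        included_terms=terms,
        rmse=float(np.sqrt(fit.ssr / dof)),
        adj_r2=float(fit.rsquared_adj),
        pd_range=(float(X["planting_doy"].min()), float(X["planting_doy"].max())),
        hd_range=(float(X["harvest_doy"].min()), float(X["harvest_doy"].max())),
    )


def predict_surface(model: SurfaceModel, pd_grid, hd_grid) -> np.ndarray:
    """Predicted EHQI over the outer grid, shape (len(pd), len(hd)).

    Warns when the grid extends beyond the fitted DOY ranges
    (extrapolation), if the model records them.
    """
    pd_grid = np.atleast_1d(np.asarray(pd_grid, dtype=float))
    hd_grid = np.atleast_1d(np.asarray(hd_grid, dtype=float))
    for grid, rng, axis in (
        (pd_grid, model.pd_range, "planting"),
        (hd_grid, model.hd_range, "harvest"),
    ):
        if rng is not None and (grid.min() < rng[0] or grid.max() > rng[1]):
            warnings.warn(
                f"{axis}-date grid extends beyond fitted range {rng}; "
                "predictions are extrapolations",
                stacklevel=2,
            )
    return model.predict(pd_grid[:, None], hd_grid[None, :])


def _require_peak(model: SurfaceModel) -> None:
    if not model.beta_hd2 < 0:
        raise ResponseSurfaceError(
            "no interior quality maximum: harvest-date curvature "
            f"beta_hd2={model.beta_hd2} is not negative"
        )


def find_peak(
    model: SurfaceModel, planting_doy: float | None = None
) -> tuple[float, float | None]:
    """Harvest DOY of peak predicted EHQI and, if a planting date is
    given (or the model has no planting terms), the peak value."""
    _require_peak(model)
    peak_hd = -model.beta_hd / (2.0 * model.beta_hd2)
    if planting_doy is None:
        if model.beta_pd == 0.0 and model.beta_pd2 == 0.0:
            planting_doy = 0.0
        else:
            return peak_hd, None
    return peak_hd, float(model.predict(planting_doy, peak_hd))


def harvest_window(
    model: SurfaceModel,
    tolerance: float,
    planting_doy: float | None = None,
) -> HarvestWindow:
    """Days of harvest slack around the peak at a given quality tolerance.

    Because the surface has no planting x harvest interaction, the
    width ``2*sqrt(tolerance/|beta_hd2|)`` is the same at every
    planting date; ``planting_doy`` only fixes the peak EHQI value.
    """
    if not tolerance > 0:
        raise ResponseSurfaceError(f"tolerance must be positive, got {tolerance}")
    peak_hd, peak_val = find_peak(model, planting_doy)
    half = float(np.sqrt(tolerance / abs(model.beta_hd2)))
    width = 2.0 * half
    return HarvestWindow(
        peak_harvest_doy=peak_hd,
        peak_ehqi=peak_val,
        tolerance=tolerance,
        window_start_doy=peak_hd - half,
        window_end_doy=peak_hd + half,
        width_days=width,
        width_days_rounded=int(round(width)),
    )
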