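"""Reference response-surface coefficients for three edamame cultivars.

Quadratic planting x harvest response surfaces for the harvest-quality
index were previously fitted (stepwise OLS) to multi-environment
Arkansas field trials of cultivars 8080 (MG3, indeterminate),
R08-4002 (MG5, determinate) and R09-345 (MG6, determinate).  The
coefficients, fit statistics and the one-standard-error tolerances
reported alongside them are reproduced here so that peak harvest days
and harvest windows can be recomputed without the raw trial data.

For R08-4002 the linear planting-date term was not significant in the
stepwise fit and carries coefficient 0.
"""

from __future__ import annotations

from .response_surface import SurfaceModel

__all__ = [
    "REFERENCE_SURFACES",
    "REFERENCE_TOLERANCES",
    "REFERENCE_WINDOW_DAYS",
]

#: Fitted quadratic surfaces per cultivar (coefficients on raw EHQI).
REFERENCE_SURFACES: dict[str, SurfaceModel] = {
    "8080": SurfaceModel(
        intercept=-5.21578,
        beta_pd=-0.02442,
        beta_pd2=0.00008,
        beta_hd=0.06083,
        beta_hd2=-0.00013,
        included_terms=(
            "planting_doy", "planting_doy_sq", "harvest_doy", "harvest_doy_sq",
        ),
        rmse=0.04861,
        adj_r2=0.50740,
    ),
    "R08-4002": SurfaceModel(
        intercept=-22.67342,
        beta_pd=0.0,
        beta_pd2=0.00001,
        beta_hd=0.17232,
        beta_hd2=-0.00033,
        included_terms=("planting_doy_sq", "harvest_doy", "harvest_doy_sq"),
        rmse=0.05957,
        adj_r2=0.42270,
    ),
    "R09-345": SurfaceModel(
        intercept=-9.80640,
        beta_pd=-0.00970,
        beta_pd2=0.00003,
        beta_hd=0.08111,
        beta_hd2=-0.00015,
        included_terms=(
            "planting_doy", "planting_doy_sq", "harvest_doy", "harvest_doy_sq",
        ),
        rmse=0.02823,
        adj_r2=0.34650,
    ),
}

#: One-standard-error quality tolerances (EHQI units) reported with the
#: fitted surfaces, used to delimit each cultivar's harvest window.
REFERENCE_TOLERANCES: dict[str, float] = {
    "8080": 0.024,
    "R08-4002": 0.026,
    "R09-345": 0.015,
}

#: Harvest-window widths (days) reported with the reference surfaces.
REFERENCE_WINDOW_DAYS: dict[str, int] = {
    "8080": 27,
    "R08-4002": 18,
    "R09-345": 20,
}
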