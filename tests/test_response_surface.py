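import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from edamame.reference import REFERENCE_SURFACES
from edamame.response_surface import (
    ResponseSurfaceError,
    SurfaceModel,
    find_peak,
    fit_surface,
    harvest_window,
    predict_surface,
)
from edamame.synthetic_data import simulate_quadratic_records

TRUE_COEFS = dict(
    intercept=-5.2, beta_pd=-0.024, beta_pd2=0.00008,
    beta_hd=0.060, beta_hd2=-0.00013,
)


def scan_window_width(model, tolerance, planting_doy=150.0, resolution=0.01):
    """Brute-force oracle: grid-scan the harvest days whose predicted
    quality stays within `tolerance` of the peak."""
    peak_hd = -model.beta_hd / (2 * model.beta_hd2)
    hd = np.arange(peak_hd - 120.0, peak_hd + 120.0, resolution)
    vals = model.predict(planting_doy, hd)
    peak = model.predict(planting_doy, peak_hd)
    inside = hd[vals >= peak - tolerance]
    return inside.max() - inside.min()


class TestFitSurface:
    def test_noiseless_quadratic_is_interpolated_exactly(self):
        df = simulate_quadratic_records(60, **TRUE_COEFS, noise_sd=0.0, seed=5)
        m = fit_surface(df, selection="full")
        for name, true in TRUE_COEFS.items():
            got = m.intercept if name == "intercept" else getattr(m, name)
            assert got == pytest.approx(true, abs=1e-9)

    def test_single_harvest_date_is_rank_deficient(self):
        df = simulate_quadratic_records(40, **TRUE_COEFS, noise_sd=0.01, seed=1)
        df["harvest_doy"] = 230.0
        with pytest.raises(ResponseSurfaceError, match="harvest_doy"):
            fit_surface(df, selection="full")

    def test_too_few_support_points_rejected(self):
        df = pd.DataFrame(
            {"planting_doy": [140, 140, 150, 150],
             "harvest_doy": [220, 230, 220, 230],
             "ehqi": [0.1, 0.2, 0.15, 0.25]}
        )
        with pytest.raises(ResponseSurfaceError, match="support"):
            fit_surface(df)

    def test_fit_invariant_to_row_order(self):
        df = simulate_quadratic_records(200, **TRUE_COEFS, noise_sd=0.05, seed=2)
        m1 = fit_surface(df, selection="full")
        m2 = fit_surface(df.sample(frac=1.0, random_state=9), selection="full")
        assert m1.beta_hd2 == pytest.approx(m2.beta_hd2, rel=1e-9)
        assert m1.intercept == pytest.approx(m2.intercept, rel=1e-9)

    def test_stepwise_can_drop_weak_linear_planting_term(self):
        # generating surface has no linear planting effect at all
        coefs = dict(TRUE_COEFS, beta_pd=0.0)
        df = simulate_quadratic_records(400, **coefs, noise_sd=0.05, seed=3)
        m = fit_surface(df, selection="stepwise")
        assert "harvest_doy_sq" in m.included_terms or m.beta_hd2 == 0.0
        # excluded terms must carry coefficient exactly 0
        for term, attr in [("planting_doy", "beta_pd"),
                           ("planting_doy_sq", "beta_pd2"),
                           ("harvest_doy", "beta_hd"),
                           ("harvest_doy_sq", "beta_hd2")]:
            if term not in m.included_terms:
                assert getattr(m, attr) == 0.0


class TestPredictSurface:
    def test_reference_surface_pointwise_evaluation(self):
        m = REFERENCE_SURFACES["8080"]
        expected = (
            -5.21578 - 0.02442 * 196 + 0.00008 * 196**2
            + 0.06083 * 234 - 0.00013 * 234**2
        )
        assert m.predict(196, 234) == pytest.approx(expected, abs=1e-12)
        grid = predict_surface(m, [196.0], [234.0])
        assert grid.shape == (1, 1)
        assert grid[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_zero_model_predicts_constant_zero(self):
        m = SurfaceModel(0.0, 0.0, 0.0, 0.0, 0.0)
        assert np.all(predict_surface(m, np.arange(130, 200), np.arange(200, 280)) == 0)

    def test_quadratic_only_model_is_symmetric_about_peak(self):
        m = SurfaceModel(0.0, 0.0, 0.0, 0.04, -0.0001)
        peak, _ = find_peak(m, planting_doy=0.0)
        left = m.predict(0.0, peak - 7.3)
        right = m.predict(0.0, peak + 7.3)
        assert left == pytest.approx(right, abs=1e-12)

    def test_extrapolation_beyond_fitted_range_warns(self):
        df = simulate_quadratic_records(100, **TRUE_COEFS, noise_sd=0.01, seed=4)
        m = fit_surface(df, selection="full")
        with pytest.warns(UserWarning, match="extrapolat"):
            predict_surface(m, [100.0], [230.0])


class TestFindPeak:
    def test_reference_closed_form_peak(self):
        m = REFERENCE_SURFACES["8080"]
        peak, _ = find_peak(m, planting_doy=196.0)
        assert peak == pytest.approx(0.06083 / (2 * 0.00013), abs=1e-9)

    def test_toy_parabola_peak(self):
        # -(hd - 200)^2 scaled: beta_hd = 2*200*c, beta_hd2 = -c
        c = 1e-4
        m = SurfaceModel(0.0, 0.0, 0.0, 2 * 200 * c, -c)
        peak, val = find_peak(m, planting_doy=0.0)
        assert peak == pytest.approx(200.0, abs=1e-9)

    def test_grid_scan_agrees_with_closed_form(self):
        m = REFERENCE_SURFACES["R09-345"]
        hd = np.arange(200.0, 340.0, 0.01)
        brute = hd[np.argmax(m.predict(196.0, hd))]
        peak, _ = find_peak(m, 196.0)
        assert abs(brute - peak) <= 0.01

    def test_non_negative_curvature_has_no_interior_maximum(self):
        m = SurfaceModel(0.0, 0.0, 0.0, 0.1, 0.00005)
        with pytest.raises(ResponseSurfaceError, match="maximum"):
            find_peak(m, 150.0)


class TestHarvestWindow:
    @given(
        st.floats(min_value=5e-5, max_value=5e-3),
        st.floats(min_value=1e-3, max_value=0.1),
    )
    def test_closed_form_width_matches_grid_scan(self, neg_curv, tolerance):
        m = SurfaceModel(0.5, 0.0, 0.0, 0.05, -neg_curv)
        w = harvest_window(m, tolerance, planting_doy=150.0)
        scanned = scan_window_width(m, tolerance)
        assert w.width_days == pytest.approx(scanned, abs=0.02)
        assert w.window_end_doy - w.window_start_doy == pytest.approx(
            w.width_days, abs=1e-12
        )

    @given(st.floats(min_value=1e-3, max_value=0.05))
    def test_width_scales_as_sqrt_of_tolerance(self, tolerance):
        m = REFERENCE_SURFACES["8080"]
        w1 = harvest_window(m, tolerance, 150.0)
        w2 = harvest_window(m, 2 * tolerance, 150.0)
        assert w2.width_days == pytest.approx(np.sqrt(2) * w1.width_days, abs=1e-9)

    def test_window_symmetric_about_peak(self):
        m = REFERENCE_SURFACES["R08-4002"]
        w = harvest_window(m, 0.026, 166.0)
        assert w.peak_harvest_doy - w.window_start_doy == pytest.approx(
            w.window_end_doy - w.peak_harvest_doy, abs=1e-12
        )

    def test_nonpositive_tolerance_rejected(self):
        with pytest.raises(ResponseSurfaceError):
            harvest_window(REFERENCE_SURFACES["8080"], 0.0, 150.0)
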