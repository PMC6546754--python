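"""NDVI phenology retrieval vs the analytic landmarks of the fitted curve."""

import numpy as np
import pytest

from phenotrend import (
    SimulationConfig,
    aggregate_hemisphere,
    extract_grid_phenology,
    fit_double_logistic,
    generate_ndvi_grid,
    mask_vegetated,
    pheno_dynamic_threshold,
    pheno_method1,
    pheno_method2,
    pheno_method5,
    seasonal_curve,
    sg_smooth,
)
from phenotrend.curves import (
    DoubleLogisticFit,
    ratio_crossing_eos,
    ratio_crossing_sos,
    second_derivative_landmarks,
)
from phenotrend.synthetic import composite_midpoints


class TestSgSmooth:
    def test_reproduces_linear_ramp(self):
        ramp = np.linspace(0.0, 1.0, 48)
        assert np.allclose(sg_smooth(ramp, 9, 2), ramp, atol=1e-12)

    def test_preserves_constant(self):
        const = np.full(30, 0.4)
        assert np.allclose(sg_smooth(const, 9, 2), const)

    def test_reduces_noise_variance(self):
        rng = np.random.default_rng(0)
        t = np.arange(96)
        noisy = np.sin(2 * np.pi * t / 24) + rng.normal(0, 0.3, t.size)
        sm = sg_smooth(noisy, 9, 2)
        assert np.var(sm - np.sin(2 * np.pi * t / 24)) < np.var(
            noisy - np.sin(2 * np.pi * t / 24)
        )

    def test_interpolates_gaps(self):
        ramp = np.linspace(0.0, 1.0, 48)
        gappy = ramp.copy()
        gappy[10] = np.nan
        assert np.allclose(sg_smooth(gappy, 9, 2), ramp, atol=1e-12)

    def test_rejects_bad_window(self):
        with pytest.raises(ValueError):
            sg_smooth(np.zeros(20), window=8, order=2)
        with pytest.raises(ValueError):
            sg_smooth(np.zeros(5), window=9, order=2)


class TestFit:
    def test_recovers_noise_free_parameters(self, ref_fit):
        mids = composite_midpoints(24)
        y = seasonal_curve(mids, *ref_fit.params)
        fit = fit_double_logistic(mids, y)
        assert fit.valid
        for est, tru in zip(fit.params, ref_fit.params):
            assert est == pytest.approx(tru, rel=1e-3)

    def test_spring_middate_stable_under_noise(self, ref_fit):
        rng = np.random.default_rng(1)
        mids = composite_midpoints(24)
        clean = seasonal_curve(mids, *ref_fit.params)
        errs = []
        for _ in range(100):
            fit = fit_double_logistic(mids, clean + rng.normal(0, 0.02, 24))
            if fit.valid:
                errs.append(abs(fit.d - 120.0))
        assert np.median(errs) < 2.0

    def test_flat_series_invalid_not_raising(self):
        mids = composite_midpoints(24)
        fit = fit_double_logistic(mids, np.full(24, 0.3) +
                                  np.linspace(0, 0.01, 24))
        assert not fit.valid


class TestLandmarkMethods:
    def test_method1_matches_closed_form(self, ref_fit):
        est = pheno_method1(ref_fit)
        lm = second_derivative_landmarks(ref_fit)
        assert est.sos == pytest.approx(lm["sos"], abs=0.5)
        assert est.eos == pytest.approx(lm["eos"], abs=0.5)
        assert est.maturity == pytest.approx(lm["maturity"], abs=0.5)
        assert est.senescence == pytest.approx(lm["senescence"], abs=0.5)

    def test_method1_landmark_ordering(self, ref_fit):
        est = pheno_method1(ref_fit)
        assert est.sos < est.maturity < est.senescence < est.eos

    def test_method1_sos_approaches_middate_for_steep_spring(self):
        fit = DoubleLogisticFit(0.2, 0.5, -2.0, 120.0, -0.12, 280.0)
        est = pheno_method1(fit)
        assert abs(est.sos - 120.0) < 2.0

    def test_method1_rejects_overlapping_limbs(self):
        fit = DoubleLogisticFit(0.2, 0.5, -0.15, 160.0, -0.12, 180.0)
        assert not pheno_method1(fit).valid

    def test_method2_hits_inflection_dates(self, ref_fit):
        est = pheno_method2(ref_fit)
        assert est.sos == pytest.approx(120.0, abs=0.5)
        assert est.eos == pytest.approx(280.0, abs=0.5)

    def test_dynamic_threshold_half_is_inflection(self, ref_fit):
        est = pheno_dynamic_threshold(ref_fit, 0.5)
        assert est.sos == pytest.approx(120.0, abs=0.5)
        assert est.eos == pytest.approx(280.0, abs=0.5)

    def test_dynamic_threshold_02_matches_logistic_inversion(self, ref_fit):
        est = pheno_dynamic_threshold(ref_fit, 0.2)
        assert est.sos == pytest.approx(ratio_crossing_sos(ref_fit, 0.2),
                                        abs=0.5)
        assert est.eos == pytest.approx(ratio_crossing_eos(ref_fit, 0.2),
                                        abs=0.5)

    def test_threshold_ordering_monotone(self, ref_fit):
        lo = pheno_dynamic_threshold(ref_fit, 0.2)
        hi = pheno_dynamic_threshold(ref_fit, 0.5)
        assert lo.sos <= hi.sos
        assert hi.eos <= lo.eos

    def test_rejects_out_of_range_ratio(self, ref_fit):
        with pytest.raises(ValueError):
            pheno_dynamic_threshold(ref_fit, 1.2)

    @pytest.mark.parametrize("shift", [-10.0, 10.0])
    def test_translation_equivariance(self, ref_fit, shift):
        moved = DoubleLogisticFit(ref_fit.a, ref_fit.b, ref_fit.c,
                                  ref_fit.d + shift, ref_fit.e,
                                  ref_fit.f + shift)
        for fn in (pheno_method1, pheno_method2,
                   lambda f: pheno_dynamic_threshold(f, 0.2),
                   lambda f: pheno_dynamic_threshold(f, 0.5)):
            base, est = fn(ref_fit), fn(moved)
            assert est.sos == pytest.approx(base.sos + shift, abs=1.0)
            assert est.eos == pytest.approx(base.eos + shift, abs=1.0)


class TestMethod5:
    def _stationary_series(self, ref_fit, n_years=5, shift=0.0):
        mids = composite_midpoints(24)
        fit = DoubleLogisticFit(ref_fit.a, ref_fit.b, ref_fit.c,
                                ref_fit.d + shift, ref_fit.e,
                                ref_fit.f + shift)
        y = seasonal_curve(mids, *fit.params)
        doy = np.tile(mids, n_years)
        values = np.tile(y, n_years)
        years = np.repeat(np.arange(2000, 2000 + n_years), mids.size)
        return doy, values, years, fit

    def test_stationary_years_identical(self, ref_fit):
        doy, values, years, _ = self._stationary_series(ref_fit)
        ests = pheno_method5(doy, values, years)
        sos = [e.sos for e in ests if e.valid]
        assert len(sos) == 5
        assert np.ptp(sos) < 1e-9

    def test_constant_series_invalid(self):
        mids = composite_midpoints(24)
        doy = np.tile(mids, 3)
        years = np.repeat([1, 2, 3], mids.size)
        ests = pheno_method5(doy, np.full(doy.size, 0.5), years)
        assert not any(e.valid for e in ests)

    def test_translation_shifts_dates(self, ref_fit):
        doy0, v0, yr0, _ = self._stationary_series(ref_fit)
        doy1, v1, yr1, _ = self._stationary_series(ref_fit, shift=10.0)
        s0 = [e.sos for e in pheno_method5(doy0, v0, yr0) if e.valid]
        s1 = [e.sos for e in pheno_method5(doy1, v1, yr1) if e.valid]
        assert np.mean(s1) - np.mean(s0) == pytest.approx(10.0, abs=1.0)


class TestGridWorkflow:
    def test_mask_thresholds_inclusive(self):
        import xarray as xr

        ndvi = np.zeros((10, 3, 1))
        ndvi[:, 0, 0] = 0.25   # below threshold
        # 0.5 is exactly representable, so the time-mean is exactly the
        # threshold and the inclusive boundary is what is being tested
        ndvi[:, 1, 0] = 0.50
        ndvi[:, 2, 0] = 0.75
        ds = xr.Dataset(
            {"ndvi": (("time", "lat", "lon"), ndvi),
             "day_of_year": (("time",), np.arange(10.0)),
             "year": (("time",), np.full(10, 2000))},
            coords={"time": np.arange(10.0), "lat": [25.0, 30.0, 60.0],
                    "lon": [0.0]},
        )
        mask = mask_vegetated(ds, ndvi_threshold=0.5).values
        assert not mask[0, 0]          # mean NDVI below the cutoff
        assert mask[1, 0]              # boundary value at 30 deg N retained
        assert mask[2, 0]
        ds2 = ds.assign_coords(lat=[25.0, 25.0, 25.0])
        assert not mask_vegetated(ds2, ndvi_threshold=0.5).values.any()

    def test_extraction_matches_truth_on_noise_free_grid(self,
                                                         noise_free_config):
        grid, truth = generate_ndvi_grid(noise_free_config)
        pheno = extract_grid_phenology(grid, methods={2, 4}, smooth=False,
                                       min_valid_methods=1)
        m2 = pheno[(pheno["method"] == "m2") & pheno["valid"]]
        # method 2 recovers the generating spring/autumn mid-dates
        assert np.allclose(m2["sos"], noise_free_config.sos0, atol=1.0)
        assert np.allclose(m2["eos"], noise_free_config.eos0, atol=1.0)

    def test_single_method_mean_equals_method(self, noise_free_config):
        grid, _ = generate_ndvi_grid(noise_free_config)
        pheno = extract_grid_phenology(grid, methods={4}, smooth=False,
                                       min_valid_methods=1)
        wide = pheno.pivot_table(index=["ilat", "ilon", "year"],
                                 columns="method", values="sos")
        assert np.allclose(wide["mean"], wide["m4"])

    def test_empty_method_set_rejected(self, noise_free_config):
        grid, _ = generate_ndvi_grid(noise_free_config)
        with pytest.raises(ValueError):
            extract_grid_phenology(grid, methods=set())

    def test_hemisphere_mean_arithmetic(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "ilat": [0, 1], "ilon": [0, 0],
                "lat": [30.0, 60.0], "lon": [0.0, 0.0],
                "year": [2000, 2000], "method": ["m4", "m4"],
                "sos": [100.0, 120.0], "eos": [280.0, 300.0],
                "valid": [True, True],
            }
        )
        out = aggregate_hemisphere(df)
        assert out["sos"].iloc[0] == pytest.approx(110.0)
        w = aggregate_hemisphere(df, cos_lat_weight=True)
        c30, c60 = np.cos(np.deg2rad(30)), np.cos(np.deg2rad(60))
        expect = (100 * c30 + 120 * c60) / (c30 + c60)
        assert w["sos"].iloc[0] == pytest.approx(expect, abs=0.05)
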