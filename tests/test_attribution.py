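"""Seasonal aggregation, (partial) correlation, and site-census summaries."""

import numpy as np
import pandas as pd
import pytest

from phenotrend import (
    SimulationConfig,
    correlate,
    flux_trend_proportions,
    generate_flux_site,
    partial_correlation,
    seasonal_aggregate,
    significance_census,
)
from phenotrend.attribution import (
    _partial_from_precision,
    partial_correlation_recursive,
)


def _monthly(rows):
    return pd.DataFrame(rows, columns=["year", "month", "TA", "TA_QC",
                                       "P", "P_QC"])


class TestSeasonalAggregate:
    def test_winter_crosses_year_boundary(self):
        rows = [
            (2000, 12, -5.0, 1.0, 10.0, 1.0),
            (2001, 1, -10.0, 1.0, 10.0, 1.0),
            (2001, 2, -9.0, 1.0, 10.0, 1.0),
        ]
        out = seasonal_aggregate(_monthly(rows), "TA", "winter")
        assert out.loc[2001] == pytest.approx(-8.0)

    def test_winter_never_double_counts_december(self):
        rows = []
        for y in (2000, 2001, 2002):
            for m in range(1, 13):
                rows.append((y, m, float(m), 1.0, 1.0, 1.0))
        out = seasonal_aggregate(_monthly(rows), "TA", "winter")
        # winter 2001 = Dec 2000 (12) + Jan 2001 (1) + Feb 2001 (2)
        assert out.loc[2001] == pytest.approx(5.0)
        # year 2000 has no previous December -> missing
        assert 2000 not in out.index or np.isnan(out.loc[2000])

    def test_precipitation_summed(self):
        rows = [(2001, 3, 0.0, 1.0, 30.0, 1.0),
                (2001, 4, 0.0, 1.0, 40.0, 1.0),
                (2001, 5, 0.0, 1.0, 50.0, 1.0)]
        out = seasonal_aggregate(_monthly(rows), "P", "spring")
        assert out.loc[2001] == pytest.approx(120.0)

    def test_low_qc_month_voids_season(self):
        rows = [(2001, 3, 1.0, 1.0, 1.0, 1.0),
                (2001, 4, 2.0, 0.5, 1.0, 1.0),
                (2001, 5, 3.0, 1.0, 1.0, 1.0)]
        out = seasonal_aggregate(_monthly(rows), "TA", "spring")
        assert np.isnan(out.loc[2001])

    def test_unknown_season_rejected(self):
        with pytest.raises(ValueError):
            seasonal_aggregate(_monthly([]), "TA", "monsoon")


class TestCorrelate:
    def test_exact_linear_coupling(self):
        ta = pd.Series(np.arange(10.0), index=range(2000, 2010))
        pheno = -3.0 * ta + 120.0
        res = correlate(pheno, ta)
        assert res.r == pytest.approx(-1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(0)
        idx = range(1000)
        a = pd.Series(rng.normal(size=1000), index=idx)
        b = pd.Series(rng.normal(size=1000), index=idx)
        assert abs(correlate(a, b).r) < 0.1

    def test_symmetry_and_affine_invariance(self):
        rng = np.random.default_rng(1)
        idx = range(30)
        a = pd.Series(rng.normal(size=30), index=idx)
        b = pd.Series(rng.normal(size=30), index=idx)
        assert correlate(a, b).r == pytest.approx(correlate(b, a).r)
        assert correlate(2.0 * a + 5.0, b).r == pytest.approx(
            correlate(a, b).r
        )

    def test_pairwise_missing_dropped(self):
        a = pd.Series([1.0, 2, 3, np.nan, 5, 6], index=range(6))
        b = pd.Series([2.0, 4, 6, 8, 10, 12], index=range(6))
        res = correlate(a, b)
        assert res.n == 5
        assert res.r == pytest.approx(1.0)

    def test_zero_variance_flagged(self):
        a = pd.Series(np.ones(8), index=range(8))
        b = pd.Series(np.arange(8.0), index=range(8))
        assert not correlate(a, b).valid


class TestPartialCorrelation:
    def test_symmetric_half_correlations(self):
        R = np.full((3, 3), 0.5)
        np.fill_diagonal(R, 1.0)
        out = _partial_from_precision(R)
        assert out[0, 1] == pytest.approx((0.5 - 0.25) / 0.75)
        rec = partial_correlation_recursive(R, 0, 1, [2])
        assert out[0, 1] == pytest.approx(rec)

    def test_matrix_route_equals_recursive_formula(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            A = rng.normal(size=(40, 4))
            R = np.corrcoef(A, rowvar=False)
            M = _partial_from_precision(R)
            for j in range(1, 4):
                controls = [k for k in range(1, 4) if k != j]
                rec = partial_correlation_recursive(R, 0, j, controls)
                assert M[0, j] == pytest.approx(rec, abs=1e-10)

    def test_independent_control_leaves_r_unchanged(self):
        rng = np.random.default_rng(3)
        n = 4000
        idx = range(n)
        x = rng.normal(size=n)
        pheno = pd.Series(x + 0.5 * rng.normal(size=n), index=idx)
        env = pd.DataFrame({"x": x, "z": rng.normal(size=n)}, index=idx)
        res = {r.variable: r for r in partial_correlation(pheno, env)}
        assert res["x"].r_partial == pytest.approx(res["x"].r, abs=0.05)

    def test_pheno_function_of_control_only(self):
        rng = np.random.default_rng(4)
        n = 2000
        idx = range(n)
        z = rng.normal(size=n)
        pheno = pd.Series(2.0 * z + 0.01 * rng.normal(size=n), index=idx)
        env = pd.DataFrame({"x": z + 0.3 * rng.normal(size=n), "z": z},
                           index=idx)
        res = {r.variable: r for r in partial_correlation(pheno, env)}
        assert abs(res["x"].r_partial) < 0.05

    def test_simulated_coupling_detected_at_most_sites(self):
        cfg = SimulationConfig(
            n_years=15, start_year=2000, breakpoint_year=2007,
            site_years=15, sos_slope_pre=0.0, sos_slope_post=0.0,
            eos_slope_pre=0.0, eos_slope_post=0.0,
            sos_temp_coupling=-3.0, ta_anomaly_sd=1.0,
            noise_sd_pheno=2.0, seed=17,
        )
        rng = np.random.default_rng(cfg.seed)
        hits = 0
        n_sites = 20
        for _ in range(n_sites):
            _, truth = generate_flux_site(cfg, rng=rng)
            sos = pd.Series(truth.true_sos, index=truth.years)
            ta = pd.Series(truth.spring_ta_anomaly, index=truth.years)
            res = correlate(sos, ta)
            if res.r < 0 and res.p < 0.05:
                hits += 1
        assert hits >= int(0.9 * n_sites)


class TestCensus:
    def test_classification_example(self):
        df = pd.DataFrame({"slope": [-1.0, -0.5, 0.7],
                           "p": [0.03, 0.2, 0.06]})
        out = significance_census(df)
        assert out["advancing"]["all"] == 2
        assert out["advancing"]["p<0.05"] == 1
        assert out["delaying"]["all"] == 1
        assert out["delaying"]["p<0.1"] == 1

    def test_counts_partition_sites(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"slope": np.r_[rng.normal(size=20), 0.0],
                           "p": rng.uniform(size=21)})
        out = significance_census(df)
        total = (out["advancing"]["all"] + out["delaying"]["all"]
                 + out["zero_slope"])
        assert total == out["n_sites"] == 21

    def test_empty_input(self):
        out = significance_census(pd.DataFrame(columns=["slope", "p"]))
        assert out["advancing"]["all"] == 0
        assert out["n_sites"] == 0


class TestFluxProportions:
    def test_proportion_arithmetic(self):
        pheno = pd.DataFrame({"site": list("abcd"),
                              "p": [0.01, 0.02, 0.03, 0.04]})
        flux = pd.DataFrame({"site": list("abcd"),
                             "variable": ["GPP"] * 4,
                             "p": [0.01, 0.02, 0.5, 0.6]})
        out = flux_trend_proportions(pheno, flux)
        row = out[(out["group"] == "with_pheno_trend")]
        assert row["proportion"].iloc[0] == pytest.approx(0.5)

    def test_empty_group_flagged(self):
        pheno = pd.DataFrame({"site": ["a"], "p": [0.01]})
        flux = pd.DataFrame({"site": ["a"], "variable": ["GPP"],
                             "p": [0.5]})
        out = flux_trend_proportions(pheno, flux)
        empty = out[out["group"] == "without_pheno_trend"]
        assert np.isnan(empty["proportion"].iloc[0])
        assert empty["n_sites"].iloc[0] == 0

    def test_no_flux_trends_gives_zero(self):
        pheno = pd.DataFrame({"site": ["a", "b"], "p": [0.01, 0.5]})
        flux = pd.DataFrame({"site": ["a", "b"], "variable": ["ER", "ER"],
                             "p": [0.9, 0.9]})
        out = flux_trend_proportions(pheno, flux)
        assert (out["proportion"].dropna() == 0).all()
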