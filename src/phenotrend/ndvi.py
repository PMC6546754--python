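"""Start/end-of-season retrieval from NDVI composite time series.

Five retrieval methods are implemented, spanning the two families in
common use:

1. **Curvature landmarks** — fit the double logistic, take the extrema of
   the second derivative on each limb (green-up onset = SOS, plus onset of
   maturity, onset of senescence and EOS).
2. **Inflection points** — dates of fastest NDVI increase / decrease
   (extrema of the first derivative of the fitted curve).
3. **Dynamic threshold 0.2** — first/last day the normalised fitted curve
   Ratio_day = (NDVI_day - NDVI_min)/(NDVI_max - NDVI_min) crosses 0.2.
4. **Dynamic threshold 0.5** — same with ratio 0.5.
5. **Fixed threshold** — thresholds taken where the multi-year mean cycle's
   relative change rate NDVI_RC = (NDVI(t+1) - NDVI(t))/NDVI(t) is extreme,
   then applied per year to degree-6 polynomial fits of each half-year.

Methods 1–4 operate on a per-year double-logistic fit; method 5 works on
the raw multi-year composite stack.  A Savitzky–Golay pre-filter and the
non-vegetated / latitude mask complete the grid workflow, which aggregates
to hemisphere-style annual mean SOS/EOS series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy.optimize import least_squares
from scipy.signal import savgol_filter
from scipy.special import expit

from .curves import DoubleLogisticFit, seasonal_curve, seasonal_curve_deriv, \
    seasonal_curve_deriv2
from .synthetic import composite_midpoints

__all__ = [
    "PhenologyEstimate",
    "sg_smooth",
    "fit_double_logistic",
    "pheno_method1",
    "pheno_method2",
    "pheno_dynamic_threshold",
    "pheno_method5",
    "change_rate_profile",
    "mask_vegetated",
    "extract_grid_phenology",
    "aggregate_hemisphere",
    "FIT_BOUNDS",
]

_DAYS = np.arange(1.0, 366.0)

#: Box bounds of the nonlinear least-squares fit (a, b, c, d, e, f).
FIT_BOUNDS = (
    np.array([-0.2, 1e-3, -1.0, 1.0, -1.0, 150.0]),
    np.array([1.0, 1.5, -0.005, 180.0, -0.005, 365.0]),
)


@dataclass
class PhenologyEstimate:
    """SOS/EOS (day of year) for one unit-year under one method."""

    method: str
    sos: float = np.nan
    eos: float = np.nan
    maturity: float = np.nan
    senescence: float = np.nan
    valid: bool = True
    year: int | None = None

    def __post_init__(self) -> None:
        if self.valid and np.isfinite(self.sos) and np.isfinite(self.eos):
            if not (1.0 <= self.sos < self.eos <= 365.0):
                self.valid = False


def sg_smooth(values: np.ndarray, window: int = 9, order: int = 2,
              axis: int = 0) -> np.ndarray:
    """Savitzky–Golay smoothing along ``axis``; NaNs interpolated first.

    The filter reproduces any polynomial of degree <= ``order`` exactly on
    every window, so trends survive while composite-level noise is damped.
    """
    values = np.asarray(values, dtype=float)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if order >= window:
        raise ValueError("order must be smaller than window")
    if window > values.shape[axis]:
        raise ValueError("window longer than the series")
    v = np.moveaxis(values, axis, 0)
    out = np.empty_like(v)
    flat = v.reshape(v.shape[0], -1)
    oflat = out.reshape(v.shape[0], -1)
    idx = np.arange(v.shape[0])
    for k in range(flat.shape[1]):
        col = flat[:, k]
        bad = ~np.isfinite(col)
        if bad.any():
            if bad.all():
                oflat[:, k] = np.nan
                continue
            col = col.copy()
            col[bad] = np.interp(idx[bad], idx[~bad], col[~bad])
        oflat[:, k] = savgol_filter(col, window, order)
    return np.moveaxis(out, 0, axis)


def _residual(p, t, y):
    a, b, c, d, e, f = p
    return a + b * (expit(-c * (t - d)) - expit(-e * (t - f))) - y


def _jacobian(p, t, y):
    a, b, c, d, e, f = p
    L1 = expit(-c * (t - d))
    L2 = expit(-e * (t - f))
    g1 = L1 * (1.0 - L1)
    g2 = L2 * (1.0 - L2)
    J = np.empty((t.size, 6))
    J[:, 0] = 1.0
    J[:, 1] = L1 - L2
    J[:, 2] = -b * (t - d) * g1
    J[:, 3] = b * c * g1
    J[:, 4] = b * (t - f) * g2
    J[:, 5] = -b * e * g2
    return J


def fit_double_logistic(doy: np.ndarray, ndvi: np.ndarray,
                        min_amplitude: float = 0.05) -> DoubleLogisticFit:
    """Bounded nonlinear least-squares fit of one pixel-year.

    Initial mid-dates come from the half-amplitude crossings of the raw
    samples; non-convergence or violated invariants give ``valid=False``
    rather than an exception.
    """
    doy = np.asarray(doy, dtype=float)
    ndvi = np.asarray(ndvi, dtype=float)
    good = np.isfinite(ndvi)
    doy, ndvi = doy[good], ndvi[good]
    invalid = DoubleLogisticFit(0.0, 1e-3, -0.1, 120.0, -0.1, 280.0,
                                rss=np.nan, valid=False)
    if doy.size < 12:
        return invalid
    lo, hi = float(ndvi.min()), float(ndvi.max())
    if hi - lo <= min_amplitude:
        return invalid

    half = (lo + hi) / 2.0
    above = ndvi >= half
    d0, f0 = 120.0, 280.0
    up = np.flatnonzero(~above[:-1] & above[1:])
    if up.size:
        d0 = float(doy[up[0]])
    down = np.flatnonzero(above[:-1] & ~above[1:])
    if down.size:
        f0 = float(doy[down[-1] + 1])
    lb, ub = FIT_BOUNDS
    x0 = np.clip(
        np.array([lo, hi - lo, -0.1, d0, -0.1, f0]), lb + 1e-9, ub - 1e-9
    )
    try:
        res = least_squares(
            _residual, x0, jac=_jacobian, bounds=(lb, ub), args=(doy, ndvi),
            method="trf", max_nfev=500,
        )
    except Exception:
        return invalid
    a, b, c, d, e, f = res.x
    fit = DoubleLogisticFit(a, b, c, d, e, f,
                            rss=float(np.sum(res.fun ** 2)),
                            valid=bool(res.success))
    if not (b > 0 and c < 0 and e < 0 and d < f):
        fit.valid = False
    return fit


def _refine_extremum(t: np.ndarray, v: np.ndarray, i: int) -> float:
    """Parabolic sub-grid refinement of a local extremum at index ``i``."""
    if i <= 0 or i >= t.size - 1:
        return float(t[i])
    denom = v[i - 1] - 2.0 * v[i] + v[i + 1]
    if denom == 0.0:
        return float(t[i])
    delta = 0.5 * (v[i - 1] - v[i + 1]) / denom
    return float(t[i] + np.clip(delta, -1.0, 1.0) * (t[1] - t[0]))


def _curve_grid(fit: DoubleLogisticFit):
    y = seasonal_curve(_DAYS, *fit.params)
    return _DAYS, y, int(np.argmax(y))


def pheno_method1(fit: DoubleLogisticFit, min_separation: float = 30.0
                  ) -> PhenologyEstimate:
    """Curvature landmarks: extrema of the second derivative per limb.

    SOS / onset of maturity sit at the max / min of y'' before the annual
    peak; onset of senescence / EOS at the min / max after it.  Overlapping
    limbs (f - d below ``min_separation`` days) are rejected.
    """
    if not fit.valid or (fit.f - fit.d) < min_separation:
        return PhenologyEstimate("m1", valid=False)
    t, y, ipk = _curve_grid(fit)
    y2 = seasonal_curve_deriv2(t, *fit.params)
    pre, post = slice(0, ipk + 1), slice(ipk, None)
    sos = _refine_extremum(t, y2, int(np.argmax(y2[pre])))
    mat = _refine_extremum(t, y2, int(np.argmin(y2[pre])))
    sen = _refine_extremum(t, y2, ipk + int(np.argmin(y2[post])))
    eos = _refine_extremum(t, y2, ipk + int(np.argmax(y2[post])))
    return PhenologyEstimate("m1", sos=sos, eos=eos,
                             maturity=mat, senescence=sen)


def pheno_method2(fit: DoubleLogisticFit, min_separation: float = 30.0
                  ) -> PhenologyEstimate:
    """Inflection points: dates of fastest NDVI increase and decrease."""
    if not fit.valid or (fit.f - fit.d) < min_separation:
        return PhenologyEstimate("m2", valid=False)
    t, y, ipk = _curve_grid(fit)
    y1 = seasonal_curve_deriv(t, *fit.params)
    sos = _refine_extremum(t, y1, int(np.argmax(y1[: ipk + 1])))
    eos = _refine_extremum(t, y1, ipk + int(np.argmin(y1[ipk:])))
    return PhenologyEstimate("m2", sos=sos, eos=eos)


def _cross_up(t, ratio, thr, stop):
    """First upward crossing of ``thr`` before index ``stop``."""
    r = ratio[: stop + 1]
    hits = np.flatnonzero((r[:-1] < thr) & (r[1:] >= thr))
    if not hits.size:
        return np.nan
    i = hits[0]
    frac = (thr - r[i]) / (r[i + 1] - r[i])
    return float(t[i] + frac * (t[i + 1] - t[i]))


def _cross_down(t, ratio, thr, start):
    """Last downward crossing of ``thr`` after index ``start``."""
    r = ratio[start:]
    hits = np.flatnonzero((r[:-1] >= thr) & (r[1:] < thr))
    if not hits.size:
        return np.nan
    i = hits[-1] + start
    frac = (ratio[i] - thr) / (ratio[i] - ratio[i + 1])
    return float(t[i] + frac * (t[i + 1] - t[i]))


def pheno_dynamic_threshold(fit: DoubleLogisticFit, ratio: float
                            ) -> PhenologyEstimate:
    """Dynamic-threshold retrieval on the normalised fitted curve.

    ratio 0.2 reproduces method 3, ratio 0.5 method 4.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie strictly in (0, 1)")
    name = "m3" if abs(ratio - 0.2) < 1e-12 else (
        "m4" if abs(ratio - 0.5) < 1e-12 else f"mthr{ratio:g}")
    if not fit.valid:
        return PhenologyEstimate(name, valid=False)
    t, y, ipk = _curve_grid(fit)
    lo, hi = float(y.min()), float(y.max())
    if hi - lo <= 0:
        return PhenologyEstimate(name, valid=False)
    norm = (y - lo) / (hi - lo)
    sos = _cross_up(t, norm, ratio, ipk)
    eos = _cross_down(t, norm, ratio, ipk)
    if not (np.isfinite(sos) and np.isfinite(eos)):
        return PhenologyEstimate(name, valid=False)
    return PhenologyEstimate(name, sos=sos, eos=eos)


def change_rate_profile(doy: np.ndarray, values: np.ndarray
                        ) -> dict | None:
    """Fixed-threshold anchors from the multi-year mean seasonal cycle.

    Computes the mean cycle on the composite grid, densifies it to daily
    resolution (seasonal-model fit, linear interpolation as fallback),
    takes the relative change rate NDVI_RC = (NDVI(t+1) - NDVI(t))/NDVI(t)
    and returns the cycle, the profile and the SOS/EOS threshold values at
    the RC extrema.  Returns None when the cycle is non-positive or has no
    unique RC extrema.
    """
    doy = np.asarray(doy, dtype=float)
    values = np.asarray(values, dtype=float)
    udoy = np.unique(doy)
    cycle = np.array([np.nanmean(values[doy == d]) for d in udoy])
    if np.any(~np.isfinite(cycle)) or np.any(cycle <= 0):
        return None
    tday = np.arange(np.ceil(udoy.min()), np.floor(udoy.max()) + 1.0)
    cyc_fit = fit_double_logistic(udoy, cycle)
    if cyc_fit.valid:
        daily_cycle = seasonal_curve(tday, *cyc_fit.params)
    else:
        daily_cycle = np.interp(tday, udoy, cycle)
    rc = np.diff(daily_cycle) / daily_cycle[:-1]
    if np.allclose(rc, rc[0]):
        return None              # e.g. a constant series
    return {
        "doy": udoy,
        "cycle": cycle,
        "tday": tday,
        "daily_cycle": daily_cycle,
        "rc": rc,
        "sos_threshold": float(daily_cycle[int(np.argmax(rc))]),
        "eos_threshold": float(daily_cycle[int(np.argmin(rc))]),
    }


def pheno_method5(doy: np.ndarray, values: np.ndarray, years: np.ndarray,
                  degree: int = 6) -> list[PhenologyEstimate]:
    """Fixed-threshold retrieval anchored on the multi-year mean cycle.

    Thresholds are the mean-cycle NDVI where the relative change rate
    NDVI_RC = (NDVI(t+1) - NDVI(t)) / NDVI(t) attains its max (SOS) and min
    (EOS), per :func:`change_rate_profile`.  Each year's transition windows
    are then fitted with a degree-6 polynomial evaluated daily, and
    crossings of the fixed thresholds give that year's dates.
    """
    doy = np.asarray(doy, dtype=float)
    values = np.asarray(values, dtype=float)
    years = np.asarray(years)
    uyears = np.unique(years)
    if uyears.size < 3:
        return [PhenologyEstimate("m5", valid=False, year=int(y))
                for y in uyears]

    profile = change_rate_profile(doy, values)
    if profile is None:
        return [PhenologyEstimate("m5", valid=False, year=int(y))
                for y in uyears]
    tday = profile["tday"]
    daily_cycle = profile["daily_cycle"]
    sos_thr = profile["sos_threshold"]
    eos_thr = profile["eos_threshold"]

    # Per-year polynomials are fitted over balanced transition windows —
    # from shortly before green-up onset (2 % of amplitude) to one
    # composite past plateau entry (90 %), and mirrored in autumn.  A
    # degree-6 polynomial asked to cover the flat background, the steep
    # limb and the plateau at once develops systematic overshoot that
    # shifts threshold crossings by several days; the trimmed window keeps
    # the crossing error below a day at composite resolution.
    lo, hi = float(daily_cycle.min()), float(daily_cycle.max())
    amp = hi - lo
    plateau = np.flatnonzero(daily_cycle >= lo + 0.9 * amp)
    active = np.flatnonzero(daily_cycle >= lo + 0.02 * amp)
    t_up_end = float(tday[plateau[0]]) + 15.0
    t_up_start = float(tday[active[0]]) - 45.0
    t_down_start = float(tday[plateau[-1]]) - 15.0
    t_down_end = float(tday[active[-1]]) + 45.0

    out = []
    for y in uyears:
        sel = years == y
        dy, vy = doy[sel], values[sel]
        ok = np.isfinite(vy)
        dy, vy = dy[ok], vy[ok]
        # widen each window away from the transition (into the flat
        # background, which barely stresses the fit) until it holds
        # enough points
        up_end, up_start = t_up_end, t_up_start
        down_start, down_end = t_down_start, t_down_end
        while ((dy >= up_start) & (dy <= up_end)).sum() < degree + 1 \
                and up_start > dy.min() - 15.0:
            up_start -= 15.0
        while ((dy >= down_start) & (dy <= down_end)).sum() < degree + 1 \
                and down_end < dy.max() + 15.0:
            down_end += 15.0
        first = (dy >= up_start) & (dy <= up_end)
        second = (dy >= down_start) & (dy <= down_end)
        if first.sum() < degree + 1 or second.sum() < degree + 1:
            out.append(PhenologyEstimate("m5", valid=False, year=int(y)))
            continue
        p1 = np.polynomial.Polynomial.fit(dy[first], vy[first], degree)
        p2 = np.polynomial.Polynomial.fit(dy[second], vy[second], degree)
        t1 = np.arange(max(1.0, dy[first].min()), up_end + 1.0)
        t2 = np.arange(down_start, min(365.0, dy[second].max()) + 1.0)
        v1 = p1(t1)
        v2 = p2(t2)
        up = np.flatnonzero((v1[:-1] < sos_thr) & (v1[1:] >= sos_thr))
        down = np.flatnonzero((v2[:-1] >= eos_thr) & (v2[1:] < eos_thr))
        if not up.size or not down.size:
            out.append(PhenologyEstimate("m5", valid=False, year=int(y)))
            continue
        i = up[0]
        sos = t1[i] + (sos_thr - v1[i]) / (v1[i + 1] - v1[i])
        j = down[0]
        eos = t2[j] + (v2[j] - eos_thr) / (v2[j] - v2[j + 1])
        out.append(PhenologyEstimate("m5", sos=float(sos), eos=float(eos),
                                     year=int(y)))
    return out


def mask_vegetated(grid: xr.Dataset, ndvi_threshold: float = 0.1,
                   lat_threshold: float = 30.0) -> xr.DataArray:
    """Cells retained iff mean NDVI >= 0.1 and latitude >= 30°N.

    Both boundaries are inclusive on the retained side.
    """
    mean_ndvi = grid["ndvi"].mean("time")
    veg = mean_ndvi >= ndvi_threshold
    return veg & (grid["lat"] >= lat_threshold)


_FIT_METHODS = {1, 2, 3, 4}


def extract_grid_phenology(
    grid: xr.Dataset,
    methods: set[int] | frozenset[int] = frozenset({1, 2, 3, 4, 5}),
    sg_window: int = 9,
    sg_order: int = 2,
    smooth: bool = True,
    min_valid_methods: int = 3,
    ndvi_threshold: float = 0.1,
    lat_threshold: float = 30.0,
) -> pd.DataFrame:
    """Run the requested retrieval methods on every vegetated cell-year.

    Returns a tidy frame (ilat, ilon, lat, lon, year, method, sos, eos,
    valid) including a cross-method ``mean`` row per cell-year, valid only
    when at least ``min_valid_methods`` methods produced a valid estimate.
    """
    methods = set(methods)
    if not methods:
        raise ValueError("at least one retrieval method must be requested")
    if not methods <= {1, 2, 3, 4, 5}:
        raise ValueError(f"unknown methods: {sorted(methods - {1, 2, 3, 4, 5})}")

    veg = mask_vegetated(grid, ndvi_threshold, lat_threshold).values
    ndvi = grid["ndvi"].values
    if smooth:
        ndvi = sg_smooth(ndvi, sg_window, sg_order, axis=0)
    doy = grid["day_of_year"].values
    yrs = grid["year"].values
    uyears = np.unique(yrs)
    lat = grid["lat"].values
    lon = grid["lon"].values

    rows = []
    need_fit = bool(methods & _FIT_METHODS)
    for i in range(veg.shape[0]):
        for j in range(veg.shape[1]):
            if not veg[i, j]:
                continue
            series = ndvi[:, i, j]
            per_year: dict[int, list[PhenologyEstimate]] = {
                int(y): [] for y in uyears
            }
            if need_fit:
                for y in uyears:
                    sel = yrs == y
                    fit = fit_double_logistic(doy[sel], series[sel])
                    ests = []
                    if 1 in methods:
                        ests.append(pheno_method1(fit))
                    if 2 in methods:
                        ests.append(pheno_method2(fit))
                    if 3 in methods:
                        ests.append(pheno_dynamic_threshold(fit, 0.2))
                    if 4 in methods:
                        ests.append(pheno_dynamic_threshold(fit, 0.5))
                    per_year[int(y)].extend(ests)
            if 5 in methods:
                for est in pheno_method5(doy, series, yrs):
                    per_year[est.year].append(est)
            for y, ests in per_year.items():
                for est in ests:
                    rows.append((i, j, lat[i], lon[j], y, est.method,
                                 est.sos, est.eos, est.valid))
                valid = [e for e in ests if e.valid]
                if len(valid) >= min_valid_methods:
                    rows.append((i, j, lat[i], lon[j], y, "mean",
                                 float(np.mean([e.sos for e in valid])),
                                 float(np.mean([e.eos for e in valid])),
                                 True))
                else:
                    rows.append((i, j, lat[i], lon[j], y, "mean",
                                 np.nan, np.nan, False))
    return pd.DataFrame(
        rows, columns=["ilat", "ilon", "lat", "lon", "year", "method",
                       "sos", "eos", "valid"],
    )


def aggregate_hemisphere(pheno: pd.DataFrame,
                         cos_lat_weight: bool = False) -> pd.DataFrame:
    """Annual spatial mean SOS/EOS over valid cells, per method.

    Unweighted by default; optional cos-latitude area weighting.
    Years with no valid cell yield NaN.
    """
    df = pheno[pheno["valid"]].copy()
    if df.empty:
        return pd.DataFrame(columns=["year", "method", "sos", "eos", "n_cells"])
    if cos_lat_weight:
        df["w"] = np.cos(np.deg2rad(df["lat"]))
    else:
        df["w"] = 1.0

    def _agg(g: pd.DataFrame) -> pd.Series:
        w = g["w"].to_numpy()
        return pd.Series(
            {
                "sos": float(np.average(g["sos"], weights=w)),
                "eos": float(np.average(g["eos"], weights=w)),
                "n_cells": int(len(g)),
            }
        )

    out = (
        df.groupby(["year", "method"])
        .apply(_agg, include_groups=False)
        .reset_index()
    )
    out["n_cells"] = out["n_cells"].astype(int)
    return out
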