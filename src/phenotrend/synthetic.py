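"""Synthetic NDVI grids and flux-site records with known phenology.

Every downstream stage of the pipeline (curve fitting, phenology
retrieval, segmented trend tests, attribution) is exercised against data
produced here, where the true start/end of growing season of every
pixel-year and site-year is known exactly.

The generator emulates two data sources:

* a 15-day-composite NDVI stack (24 composites per 365-day year) whose
  per-year green-up and senescence mid-dates follow piecewise-linear
  trajectories with a configurable breakpoint ("hiatus onset") year, plus
  Gaussian inter-annual jitter and additive observation noise; a
  configurable fraction of cells is non-vegetated (flat NDVI < 0.1);
* daily eddy-covariance style site records: GPP built from the same
  double-logistic shape scaled to ``gpp_max``, two correlated GPP variants
  (standing in for the two flux-partitioning estimates), ecosystem
  respiration and NEE consistent by construction (NEE = ER - GPP), daily
  QC flags, random gaps, and monthly meteorology whose spring/autumn air
  temperature anomalies are linearly coupled to the site's SOS/EOS.

All stochastic draws flow from a single ``numpy.random.default_rng(seed)``
so identical configurations give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .curves import seasonal_curve

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SiteGroundTruth",
    "composite_windows",
    "composite_midpoints",
    "phenology_trajectory",
    "generate_ndvi_grid",
    "generate_flux_site",
    "generate_flux_network",
    "MONTH_LENGTHS",
    "doy_to_month",
]

#: Month lengths of the 365-day model year (no leap days).
MONTH_LENGTHS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
_MONTH_EDGES = np.concatenate([[0], np.cumsum(MONTH_LENGTHS)])


def doy_to_month(doy: np.ndarray) -> np.ndarray:
    """Map 1-based day-of-year to 1-based month in the 365-day calendar."""
    return np.searchsorted(_MONTH_EDGES, np.asarray(doy), side="left").astype(int)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic phenology world.

    Trend magnitudes default to the hemisphere-scale NDVI phenology slopes
    of the motivating analysis (SOS -0.337 / -0.020 and EOS +0.256 /
    -0.027 days yr⁻¹ before/after the 1998 breakpoint).
    """

    n_years: int = 33
    start_year: int = 1982
    breakpoint_year: int = 1998
    n_lat: int = 10
    n_lon: int = 10
    lat_min: float = 30.0
    lat_max: float = 70.0
    composites_per_year: int = 24
    # phenology trajectories (day of year, days per year)
    sos0: float = 125.0
    eos0: float = 280.0
    sos_slope_pre: float = -0.337
    sos_slope_post: float = -0.020
    eos_slope_pre: float = 0.256
    eos_slope_post: float = -0.027
    # seasonal curve shape
    ndvi_background: float = 0.2
    ndvi_amplitude: float = 0.5
    spring_rate: float = -0.15
    autumn_rate: float = -0.12
    # stochastic terms
    noise_sd_ndvi: float = 0.02
    noise_sd_pheno: float = 1.0
    frac_nonveg: float = 0.1
    # flux-site parameters
    n_sites: int = 10
    site_years: int = 15
    gpp_max: float = 10.0
    gpp_noise_sd: float = 0.5
    gap_fraction: float = 0.05
    qc_good_fraction: float | Sequence[float] = 0.95
    gpp_variant_corr: float = 0.95
    er_fraction: float = 0.6
    er_base: float = 0.5
    # meteorology coupling (days per °C of seasonal Tair anomaly)
    sos_temp_coupling: float = -3.0
    eos_temp_coupling: float = 2.0
    ta_anomaly_sd: float = 1.0
    ta_mean: float = 8.0
    ta_seasonal_amplitude: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_years < 3:
            raise ValueError("n_years must be >= 3")
        if not (1 <= self.sos0 < self.eos0 <= 365):
            raise ValueError("require 1 <= sos0 < eos0 <= 365")
        if not (self.start_year <= self.breakpoint_year
                <= self.start_year + self.n_years - 1):
            raise ValueError("breakpoint_year must fall inside the simulated span")
        if self.n_lat < 1 or self.n_lon < 1:
            raise ValueError("grid must have at least one cell")
        if not 1 <= self.composites_per_year <= 365:
            raise ValueError("composites_per_year must be in [1, 365]")
        for name in ("frac_nonveg", "gap_fraction", "gpp_variant_corr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.gap_fraction >= 1.0:
            raise ValueError("gap_fraction must be < 1")
        qc = np.atleast_1d(np.asarray(self.qc_good_fraction, dtype=float))
        if np.any((qc < 0) | (qc > 1)):
            raise ValueError("qc_good_fraction must lie in [0, 1]")
        if self.ndvi_amplitude <= 0:
            raise ValueError("ndvi_amplitude must be positive")
        if self.spring_rate >= 0 or self.autumn_rate >= 0:
            raise ValueError("logistic rate parameters must be negative")

    @property
    def years(self) -> np.ndarray:
        return self.start_year + np.arange(self.n_years)

    def with_(self, **kwargs) -> "SimulationConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class GroundTruth:
    """True phenology behind a generated NDVI grid.

    ``true_sos``/``true_eos`` hold the realised (jittered) spring/autumn
    mid-dates of the generating curve, shaped (year, lat, lon); non-veg
    cells are NaN.  Injected slopes are stored exactly as configured.
    """

    years: np.ndarray
    true_sos: np.ndarray
    true_eos: np.ndarray
    vegetated: np.ndarray
    slopes: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        ny, nlat, nlon = self.true_sos.shape
        yy, ii, jj = np.meshgrid(
            np.arange(ny), np.arange(nlat), np.arange(nlon), indexing="ij"
        )
        return pd.DataFrame(
            {
                "year": self.years[yy.ravel()],
                "ilat": ii.ravel(),
                "ilon": jj.ravel(),
                "true_sos": self.true_sos.ravel(),
                "true_eos": self.true_eos.ravel(),
            }
        )


@dataclass
class SiteGroundTruth:
    """True phenology and drivers behind a generated flux site."""

    site_id: str
    years: np.ndarray
    true_sos: np.ndarray           # spring mid-date d of the latent curve
    true_eos: np.ndarray           # autumn mid-date f
    true_sos_cross: np.ndarray     # noise-free 15 %-of-max GPP crossing
    true_eos_cross: np.ndarray
    spring_ta_anomaly: np.ndarray
    autumn_ta_anomaly: np.ndarray
    slopes: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site": self.site_id,
                "year": self.years,
                "true_sos": self.true_sos,
                "true_eos": self.true_eos,
                "true_sos_cross": self.true_sos_cross,
                "true_eos_cross": self.true_eos_cross,
                "spring_ta_anomaly": self.spring_ta_anomaly,
                "autumn_ta_anomaly": self.autumn_ta_anomaly,
            }
        )


def composite_windows(composites_per_year: int = 24) -> np.ndarray:
    """(start, end) day-of-year of each composite window, both inclusive.

    Window k (1-based) covers days ceil(365(k-1)/K)+1 .. ceil(365k/K).
    """
    k = np.arange(composites_per_year + 1)
    edges = np.ceil(365 * k / composites_per_year).astype(int)
    return np.stack([edges[:-1] + 1, edges[1:]], axis=1)


def composite_midpoints(composites_per_year: int = 24) -> np.ndarray:
    """Mid-date (day of year, possibly half-integral) of each composite."""
    w = composite_windows(composites_per_year)
    return (w[:, 0] + w[:, 1]) / 2.0


def phenology_trajectory(
    config: SimulationConfig, baseline: float, slope_pre: float,
    slope_post: float, n_years: int | None = None,
) -> np.ndarray:
    """Piecewise-linear phenology trajectory with a breakpoint.

    Continuous at the breakpoint: value(n) = baseline + slope_pre*n up to
    the breakpoint index, then accumulates at slope_post.
    """
    n = np.arange(config.n_years if n_years is None else n_years,
                  dtype=float)
    nb = config.breakpoint_year - config.start_year
    return baseline + np.where(
        n <= nb, slope_pre * n, slope_pre * nb + slope_post * (n - nb)
    )


def generate_ndvi_grid(config: SimulationConfig) -> tuple[xr.Dataset, GroundTruth]:
    """Simulate a (time, lat, lon) NDVI composite stack with known truth."""
    rng = np.random.default_rng(config.seed)
    ny, nlat, nlon = config.n_years, config.n_lat, config.n_lon
    K = config.composites_per_year
    mids = composite_midpoints(K)

    lat = np.linspace(config.lat_min, config.lat_max, nlat)
    lon = np.linspace(0.0, 10.0 * max(nlon - 1, 1), nlon)

    ncells = nlat * nlon
    n_nonveg = int(round(config.frac_nonveg * ncells))
    nonveg_flat = rng.choice(ncells, size=n_nonveg, replace=False)
    vegetated = np.ones(ncells, dtype=bool)
    vegetated[nonveg_flat] = False
    vegetated = vegetated.reshape(nlat, nlon)

    sos_traj = phenology_trajectory(
        config, config.sos0, config.sos_slope_pre, config.sos_slope_post
    )
    eos_traj = phenology_trajectory(
        config, config.eos0, config.eos_slope_pre, config.eos_slope_post
    )

    jitter_sos = rng.normal(0.0, config.noise_sd_pheno, size=(ny, nlat, nlon))
    jitter_eos = rng.normal(0.0, config.noise_sd_pheno, size=(ny, nlat, nlon))
    true_sos = sos_traj[:, None, None] + jitter_sos
    true_eos = eos_traj[:, None, None] + jitter_eos

    ndvi = np.empty((ny * K, nlat, nlon))
    a, b = config.ndvi_background, config.ndvi_amplitude
    for iy in range(ny):
        sl = slice(iy * K, (iy + 1) * K)
        # broadcast the curve over cells: (K, nlat, nlon)
        d = true_sos[iy][None, :, :]
        f = true_eos[iy][None, :, :]
        t = mids[:, None, None]
        ndvi[sl] = seasonal_curve(t, a, b, config.spring_rate, d,
                                  config.autumn_rate, f)

    # non-vegetated cells: flat low NDVI, guaranteed mean < 0.1
    flat = rng.uniform(0.02, 0.08, size=ncells).reshape(nlat, nlon)
    ndvi[:, ~vegetated] = flat[~vegetated][None, :]

    ndvi += rng.normal(0.0, config.noise_sd_ndvi, size=ndvi.shape)
    np.clip(ndvi, 0.0, 1.0, out=ndvi)

    year = np.repeat(config.years, K)
    doy = np.tile(mids, ny)
    time = (year - config.start_year) * 365.0 + doy

    ds = xr.Dataset(
        {
            "ndvi": (("time", "lat", "lon"), ndvi),
            "day_of_year": (("time",), doy),
            "year": (("time",), year),
        },
        coords={"time": time, "lat": lat, "lon": lon},
        attrs={
            "title": "synthetic NDVI composite stack",
            "composites_per_year": K,
            "seed": config.seed,
        },
    )

    truth_sos = np.where(vegetated[None, :, :], true_sos, np.nan)
    truth_eos = np.where(vegetated[None, :, :], true_eos, np.nan)
    truth = GroundTruth(
        years=config.years,
        true_sos=truth_sos,
        true_eos=truth_eos,
        vegetated=vegetated,
        slopes={
            "sos_pre": config.sos_slope_pre,
            "sos_post": config.sos_slope_post,
            "eos_pre": config.eos_slope_pre,
            "eos_post": config.eos_slope_post,
        },
    )
    return ds, truth


def _latent_gpp(config: SimulationConfig, d: float, f: float,
                t: np.ndarray) -> np.ndarray:
    """Noise-free daily GPP shape for one year (g C m⁻² day⁻¹)."""
    shape = seasonal_curve(t, 0.0, 1.0, config.spring_rate, d,
                           config.autumn_rate, f)
    return config.gpp_max * shape


def _threshold_crossings(values: np.ndarray, threshold: float,
                         t: np.ndarray) -> tuple[float, float]:
    """First upward / last downward linear-interpolated threshold crossing."""
    above = values >= threshold
    if not above.any() or above.all():
        return np.nan, np.nan
    idx = np.flatnonzero(~above[:-1] & above[1:])
    sos = np.nan
    if idx.size:
        i = idx[0]
        frac = (threshold - values[i]) / (values[i + 1] - values[i])
        sos = t[i] + frac * (t[i + 1] - t[i])
    idx = np.flatnonzero(above[:-1] & ~above[1:])
    eos = np.nan
    if idx.size:
        i = idx[-1]
        frac = (values[i] - threshold) / (values[i] - values[i + 1])
        eos = t[i] + frac * (t[i + 1] - t[i])
    return float(sos), float(eos)


def generate_flux_site(
    config: SimulationConfig, site_id: str = "SY-N01",
    rng: np.random.Generator | None = None,
) -> tuple["FluxSiteRecord", SiteGroundTruth]:
    """Simulate one flux site: daily carbon fluxes plus monthly meteorology."""
    from .flux import FluxSiteRecord  # local import to avoid a cycle

    if rng is None:
        rng = np.random.default_rng(config.seed)
    ny = config.site_years
    years = config.start_year + np.arange(ny)
    t = np.arange(1, 366, dtype=float)

    sos_traj = phenology_trajectory(
        config, config.sos0, config.sos_slope_pre, config.sos_slope_post,
        n_years=ny,
    )
    eos_traj = phenology_trajectory(
        config, config.eos0, config.eos_slope_pre, config.eos_slope_post,
        n_years=ny,
    )

    spring_anom = rng.normal(0.0, config.ta_anomaly_sd, ny)
    autumn_anom = rng.normal(0.0, config.ta_anomaly_sd, ny)
    true_sos = (sos_traj + config.sos_temp_coupling * spring_anom
                + rng.normal(0.0, config.noise_sd_pheno, ny))
    true_eos = (eos_traj + config.eos_temp_coupling * autumn_anom
                + rng.normal(0.0, config.noise_sd_pheno, ny))

    latent = np.concatenate(
        [_latent_gpp(config, true_sos[i], true_eos[i], t) for i in range(ny)]
    )
    ndays = latent.size

    # correlated noise pair for the two GPP variants
    rho = config.gpp_variant_corr
    z_shared = rng.normal(size=ndays)
    z1 = rng.normal(size=ndays)
    z2 = rng.normal(size=ndays)
    w = np.sqrt(rho)
    v = np.sqrt(1.0 - rho)
    e1 = w * z_shared + v * z1
    e2 = w * z_shared + v * z2
    gpp_ref = latent + config.gpp_noise_sd * e1
    gpp_alt = latent + config.gpp_noise_sd * e2
    er = config.er_fraction * gpp_ref + config.er_base
    nee = er - gpp_ref

    # daily QC flags: per-year fraction of good days
    qc_frac = np.broadcast_to(
        np.atleast_1d(np.asarray(config.qc_good_fraction, dtype=float)), (ny,)
    ) if np.ndim(config.qc_good_fraction) == 0 else np.asarray(
        config.qc_good_fraction, dtype=float
    )
    if qc_frac.size != ny:
        qc_frac = np.resize(qc_frac, ny)
    qc = np.zeros(ndays)
    for i in range(ny):
        ngood = int(round(qc_frac[i] * 365))
        good = rng.choice(365, size=ngood, replace=False)
        qc[i * 365 + good] = 1.0

    # gaps
    if config.gap_fraction > 0:
        ngap = int(round(config.gap_fraction * ndays))
        gaps = rng.choice(ndays, size=ngap, replace=False)
        for col in (gpp_ref, gpp_alt, nee, er):
            col[gaps] = np.nan

    doy = np.tile(t.astype(int), ny)
    yr = np.repeat(years, 365)
    daily = pd.DataFrame(
        {
            "year": yr,
            "doy": doy,
            "GPP_REF": gpp_ref,
            "GPP_ALT": gpp_alt,
            "NEE": nee,
            "ER": er,
            "QC": qc,
        }
    )

    # monthly meteorology; seasonal Tair anomalies couple back to phenology
    months = np.arange(1, 13)
    mid_doy = (_MONTH_EDGES[:-1] + _MONTH_EDGES[1:]) / 2.0
    ta_clim = config.ta_mean - config.ta_seasonal_amplitude * np.cos(
        2.0 * np.pi * (mid_doy - 15.0) / 365.0
    )
    rows = []
    for i, y in enumerate(years):
        ta = ta_clim + rng.normal(0.0, 0.3, 12)
        ta[2:5] += spring_anom[i]       # Mar-May
        ta[8:11] += autumn_anom[i]      # Sep-Nov
        ts = 0.8 * ta + 1.0 + rng.normal(0.0, 0.3, 12)
        vpd = np.clip(2.0 + 0.45 * ta + rng.normal(0.0, 0.5, 12), 0.05, None)
        p = np.clip(rng.normal(55.0, 20.0, 12), 0.0, None)
        sw = np.clip(
            160.0 - 120.0 * np.cos(2.0 * np.pi * (mid_doy - 172.0 + 171.0) / 365.0)
            + rng.normal(0.0, 10.0, 12),
            5.0,
            None,
        )
        swc = np.clip(30.0 - 0.08 * p.cumsum() / 12 + rng.normal(0.0, 2.0, 12),
                      5.0, 60.0)
        for j, m in enumerate(months):
            rows.append(
                {
                    "year": y, "month": m,
                    "TA": ta[j], "TS": ts[j], "VPD": vpd[j], "P": p[j],
                    "SW_IN": sw[j], "SWC": swc[j],
                    "TA_QC": 1.0, "TS_QC": 1.0, "VPD_QC": 1.0,
                    "P_QC": 1.0, "SW_IN_QC": 1.0, "SWC_QC": 1.0,
                }
            )
    monthly = pd.DataFrame(rows)

    # ground-truth 15 %-of-max crossings on the noise-free latent curve
    latent_max = max(
        _latent_gpp(config, true_sos[i], true_eos[i], t).max() for i in range(ny)
    )
    thr = 0.15 * latent_max
    sos_cross = np.empty(ny)
    eos_cross = np.empty(ny)
    for i in range(ny):
        lat_y = _latent_gpp(config, true_sos[i], true_eos[i], t)
        sos_cross[i], eos_cross[i] = _threshold_crossings(lat_y, thr, t)

    record = FluxSiteRecord(site_id=site_id, daily=daily, monthly=monthly)
    truth = SiteGroundTruth(
        site_id=site_id,
        years=years,
        true_sos=true_sos,
        true_eos=true_eos,
        true_sos_cross=sos_cross,
        true_eos_cross=eos_cross,
        spring_ta_anomaly=spring_anom,
        autumn_ta_anomaly=autumn_anom,
        slopes={
            "sos_pre": config.sos_slope_pre,
            "sos_post": config.sos_slope_post,
            "eos_pre": config.eos_slope_pre,
            "eos_post": config.eos_slope_post,
        },
    )
    return record, truth


def generate_flux_network(
    config: SimulationConfig,
) -> tuple[list, list[SiteGroundTruth]]:
    """Simulate ``config.n_sites`` independent sites from one seed stream."""
    rng = np.random.default_rng(config.seed)
    records, truths = [], []
    for k in range(config.n_sites):
        rec, tr = generate_flux_site(config, site_id=f"SY-N{k + 1:02d}", rng=rng)
        records.append(rec)
        truths.append(tr)
    return records, truths
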