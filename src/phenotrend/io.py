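"""File I/O for the pipeline's standard formats.

NetCDF (classic format via xarray's scipy backend) carries the NDVI
composite stacks; FLUXNET-style CSVs carry daily carbon fluxes and monthly
meteorology with the conventional -9999 missing sentinel and YYYYMMDD
timestamps on a 365-day calendar.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from .flux import FluxSiteRecord
from .synthetic import MONTH_LENGTHS, doy_to_month

logger = logging.getLogger("phenotrend")

MISSING = -9999.0

__all__ = [
    "MISSING",
    "PipelineConfig",
    "write_ndvi_netcdf",
    "read_ndvi_netcdf",
    "write_flux_csv",
    "read_flux_csv",
]

_MONTH_STARTS = np.concatenate([[0], np.cumsum(MONTH_LENGTHS)])[:-1]


@dataclass
class PipelineConfig:
    """End-to-end run configuration; defaults mirror the reference analysis."""

    output_dir: str = "phenotrend_output"
    ndvi_path: str | None = None
    flux_daily_paths: list = field(default_factory=list)
    flux_monthly_paths: list = field(default_factory=list)
    simulate: bool = True
    breakpoint_year: int = 1998
    methods: list = field(default_factory=lambda: [1, 2, 3, 4, 5])
    sg_window: int = 9
    sg_order: int = 2
    gpp_threshold_frac: float = 0.15
    significance_levels: list = field(default_factory=lambda: [0.05, 0.1])
    seed: int = 0
    verbosity: str = "INFO"
    simulation: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def write_ndvi_netcdf(grid: xr.Dataset, path: str | Path) -> None:
    """Write an NDVI stack to classic NetCDF (scipy backend)."""
    grid.to_netcdf(path, engine="scipy")


def read_ndvi_netcdf(path: str | Path) -> xr.Dataset:
    """Read an NDVI stack, validating the coordinates the pipeline needs."""
    ds = xr.load_dataset(path, engine="scipy")
    for name in ("time", "lat", "lon"):
        if name not in ds.coords and name not in ds.dims:
            raise ValueError(f"NetCDF file {path} lacks coordinate '{name}'")
    if "ndvi" not in ds:
        raise ValueError(f"NetCDF file {path} lacks variable 'ndvi'")
    if "day_of_year" not in ds or "year" not in ds:
        raise ValueError(
            f"NetCDF file {path} lacks 'day_of_year'/'year' time metadata"
        )
    return ds


def _timestamp(year: np.ndarray, doy: np.ndarray) -> np.ndarray:
    month = doy_to_month(doy)
    day = np.asarray(doy) - _MONTH_STARTS[month - 1]
    return year * 10000 + month * 100 + day


def write_flux_csv(record: FluxSiteRecord, daily_path: str | Path,
                   monthly_path: str | Path) -> None:
    """Write a site's daily and monthly tables in the FLUXNET-style dialect."""
    d = record.daily.copy()
    d["TIMESTAMP"] = _timestamp(d.pop("year").to_numpy(),
                                d.pop("doy").to_numpy())
    cols = ["TIMESTAMP", "GPP_REF", "GPP_ALT", "NEE", "ER", "QC"]
    d = d[cols].fillna(MISSING)
    d.to_csv(daily_path, index=False, float_format="%.6f")

    m = record.monthly.copy()
    m["TIMESTAMP"] = m.pop("year") * 100 + m.pop("month")
    front = ["TIMESTAMP"]
    m = m[front + [c for c in m.columns if c not in front]].fillna(MISSING)
    m.to_csv(monthly_path, index=False, float_format="%.6f")


def _parse_timestamp(ts: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """YYYYMMDD -> (year, doy, ok) on the 365-day calendar."""
    ts = np.asarray(ts, dtype=np.int64)
    year = ts // 10000
    month = (ts // 100) % 100
    day = ts % 100
    ok = (month >= 1) & (month <= 12)
    safe_month = np.where(ok, month, 1)
    ok &= (day >= 1) & (day <= MONTH_LENGTHS[safe_month - 1])
    doy = _MONTH_STARTS[safe_month - 1] + day
    return year, doy, ok


def read_flux_csv(daily_path: str | Path, monthly_path: str | Path,
                  site_id: str | None = None) -> FluxSiteRecord:
    """Read a site record, mapping the -9999 sentinel to missing values.

    Rows with malformed timestamps are dropped (counted in the log);
    absent meteorology columns are tolerated and simply left out.
    """
    if site_id is None:
        site_id = Path(daily_path).stem
    d = pd.read_csv(daily_path)
    if "TIMESTAMP" not in d.columns:
        raise ValueError(f"{daily_path}: missing TIMESTAMP column")
    year, doy, ok = _parse_timestamp(d["TIMESTAMP"].to_numpy())
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("%s: dropped %d rows with malformed TIMESTAMP",
                       daily_path, n_bad)
    d = d.loc[ok].copy()
    d["year"], d["doy"] = year[ok], doy[ok]
    d = d.drop(columns=["TIMESTAMP"])
    d = d.replace(MISSING, np.nan)
    for col in ("GPP_REF", "GPP_ALT", "NEE", "ER", "QC"):
        if col not in d.columns:
            logger.warning("%s: column %s absent", daily_path, col)
            d[col] = np.nan
    d = d[["year", "doy", "GPP_REF", "GPP_ALT", "NEE", "ER", "QC"]]

    m = pd.read_csv(monthly_path)
    if "TIMESTAMP" not in m.columns:
        raise ValueError(f"{monthly_path}: missing TIMESTAMP column")
    m["year"] = m["TIMESTAMP"] // 100
    m["month"] = m["TIMESTAMP"] % 100
    m = m.drop(columns=["TIMESTAMP"]).replace(MISSING, np.nan)
    front = ["year", "month"]
    m = m[front + [c for c in m.columns if c not in front]]
    return FluxSiteRecord(site_id=site_id, daily=d.reset_index(drop=True),
                          monthly=m)
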