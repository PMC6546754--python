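"""End-to-end orchestration: simulate → extract → trend → attribute.

``run_pipeline`` wires the stages together, writes every intermediate
table, and leaves a manifest (config echo, seed, library versions, counts)
so a run can be audited and reproduced byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .attribution import (
    correlate,
    partial_correlation,
    seasonal_aggregate,
    significance_census,
)
from .flux import gpp_threshold_phenology, select_sites, threshold_sensitivity
from .io import PipelineConfig, read_flux_csv, read_ndvi_netcdf, \
    write_flux_csv, write_ndvi_netcdf
from .ndvi import aggregate_hemisphere, extract_grid_phenology
from .synthetic import SimulationConfig, generate_flux_network, \
    generate_ndvi_grid
from .trends import segmented_trends, trend_test

logger = logging.getLogger("phenotrend")

#: Environmental drivers examined per phenophase (mirrors the season split:
#: SOS against spring/winter conditions, EOS against summer/autumn).
PHENOPHASE_SEASONS = {
    "sos": ("spring", "winter"),
    "eos": ("autumn", "summer"),
}
MET_VARIABLES = ("TA", "TS", "VPD", "P", "SW_IN", "SWC")


def _trend_row(res, **labels) -> dict:
    return {
        **labels,
        "slope": res.slope, "intercept": res.intercept, "p": res.p,
        "tau_b": res.tau_b, "n": res.n_used, "valid": res.valid,
        "start": res.window[0] if res.window else np.nan,
        "end": res.window[1] if res.window else np.nan,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write all outputs under output_dir."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "versions": _versions(),
        "counts": {},
    }

    # --- inputs -----------------------------------------------------------
    if config.simulate:
        sim = SimulationConfig(seed=config.seed, **config.simulation)
        if not (sim.start_year <= config.breakpoint_year
                <= sim.start_year + sim.n_years - 1):
            raise ValueError("breakpoint_year outside the simulated span")
        logger.info("simulating NDVI grid %dx%d, %d years",
                    sim.n_lat, sim.n_lon, sim.n_years)
        grid, truth = generate_ndvi_grid(sim)
        write_ndvi_netcdf(grid, out / "ndvi.nc")
        truth.to_frame().to_csv(out / "ground_truth_grid.csv", index=False)
        records, site_truths = generate_flux_network(sim)
        for rec in records:
            write_flux_csv(rec, out / f"{rec.site_id}_daily.csv",
                           out / f"{rec.site_id}_monthly.csv")
        pd.concat([t.to_frame() for t in site_truths]).to_csv(
            out / "ground_truth_sites.csv", index=False
        )
    else:
        if config.ndvi_path is None:
            raise ValueError("ndvi_path required when simulate is false")
        grid = read_ndvi_netcdf(config.ndvi_path)
        records = [
            read_flux_csv(dp, mp)
            for dp, mp in zip(config.flux_daily_paths,
                              config.flux_monthly_paths)
        ]

    years = np.unique(np.asarray(grid["year"].values))
    if not (years.min() <= config.breakpoint_year <= years.max()):
        raise ValueError("breakpoint_year outside the NDVI record span")

    # --- NDVI phenology ---------------------------------------------------
    logger.info("extracting NDVI phenology (methods %s)", config.methods)
    pheno = extract_grid_phenology(
        grid, methods=set(config.methods),
        sg_window=config.sg_window, sg_order=config.sg_order,
    )
    pheno.to_csv(out / "grid_phenology.csv", index=False)
    hemi = aggregate_hemisphere(pheno)
    hemi.to_csv(out / "hemisphere_series.csv", index=False)
    manifest["counts"]["grid_cell_years"] = int(
        pheno[pheno["method"] != "mean"].shape[0]
    )
    manifest["counts"]["phenology_methods"] = len(config.methods)

    # --- segmented trends on the hemisphere series ------------------------
    rows = []
    for method, g in hemi.groupby("method"):
        g = g.sort_values("year")
        for phase in ("sos", "eos"):
            pre, post = segmented_trends(
                g["year"].to_numpy(), g[phase].to_numpy(),
                config.breakpoint_year,
            )
            rows.append(_trend_row(pre, method=method, phenophase=phase,
                                   period="pre"))
            rows.append(_trend_row(post, method=method, phenophase=phase,
                                   period="post"))
    trend_table = pd.DataFrame(rows)
    trend_table.to_csv(out / "hemisphere_trends.csv", index=False)

    # --- flux phenology ---------------------------------------------------
    selections = select_sites(records)
    pd.DataFrame([vars(s) for s in selections]).to_csv(
        out / "site_selection.csv", index=False
    )
    qualified = {s.site_id for s in selections if s.qualifies}
    manifest["counts"]["sites_total"] = len(records)
    manifest["counts"]["sites_qualified"] = len(qualified)

    site_pheno = []
    for rec in records:
        if rec.site_id not in qualified:
            continue
        site_pheno.append(
            gpp_threshold_phenology(rec, config.gpp_threshold_frac)
        )
    site_pheno = pd.concat(site_pheno) if site_pheno else pd.DataFrame(
        columns=["site", "year", "sos", "eos", "threshold", "valid"]
    )
    site_pheno.to_csv(out / "site_phenology.csv", index=False)

    sens = [
        threshold_sensitivity(rec).assign(site=rec.site_id)
        for rec in records if rec.site_id in qualified
    ]
    if sens:
        pd.concat(sens).to_csv(out / "threshold_sensitivity.csv", index=False)

    # --- per-site trends + attribution ------------------------------------
    site_trend_rows, assoc_rows, flux_trend_rows = [], [], []
    for rec in records:
        if rec.site_id not in qualified:
            continue
        sp = site_pheno[(site_pheno["site"] == rec.site_id)
                        & site_pheno["valid"]]
        if sp.empty:
            continue
        for phase in ("sos", "eos"):
            series = sp.set_index("year")[phase]
            res = trend_test(series.index.to_numpy(), series.to_numpy())
            site_trend_rows.append(
                _trend_row(res, site=rec.site_id, phenophase=phase)
            )
            env = {}
            for season in PHENOPHASE_SEASONS[phase]:
                for var in MET_VARIABLES:
                    if var not in rec.monthly.columns:
                        continue
                    env_series = seasonal_aggregate(rec.monthly, var, season)
                    assoc = correlate(series, env_series, site=rec.site_id,
                                      phenophase=phase, variable=var,
                                      season=season)
                    assoc_rows.append(vars(assoc))
                    env[f"{var}_{season}"] = env_series
            # partial correlation of temperature vs the other drivers of
            # the phenophase's primary season
            primary = PHENOPHASE_SEASONS[phase][0]
            block = pd.DataFrame(
                {k: v for k, v in env.items() if k.endswith(primary)}
            )
            if block.shape[1] >= 2:
                for pres in partial_correlation(series, block,
                                                site=rec.site_id,
                                                phenophase=phase):
                    row = vars(pres)
                    row["season"] = primary
                    assoc_rows.append(row)
        # seasonal carbon-flux trends (spring for SOS season, autumn for EOS)
        daily = rec.daily.copy()
        daily["month"] = _month_of(daily["doy"].to_numpy())
        for var in ("GPP_REF", "NEE", "ER"):
            for season in ("spring", "autumn"):
                months = {"spring": (3, 4, 5), "autumn": (9, 10, 11)}[season]
                seas = (
                    daily[daily["month"].isin(months)]
                    .groupby("year")[var].sum(min_count=60)
                )
                res = trend_test(seas.index.to_numpy(), seas.to_numpy())
                flux_trend_rows.append(
                    _trend_row(res, site=rec.site_id, variable=var,
                               season=season)
                )

    site_trends = pd.DataFrame(site_trend_rows)
    site_trends.to_csv(out / "site_trends.csv", index=False)
    pd.DataFrame(assoc_rows).to_csv(out / "associations.csv", index=False)
    pd.DataFrame(flux_trend_rows).to_csv(out / "flux_trends.csv", index=False)

    census = {}
    if not site_trends.empty:
        for phase in ("sos", "eos"):
            sub = site_trends[site_trends["phenophase"] == phase]
            census[phase] = significance_census(sub)
    (out / "census.json").write_text(json.dumps(census, indent=2,
                                                sort_keys=True))
    manifest["counts"]["census"] = census

    cfg_bytes = json.dumps(config.to_dict(), sort_keys=True).encode()
    manifest["config_sha256"] = hashlib.sha256(cfg_bytes).hexdigest()
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    logger.info("pipeline complete: %s", out)
    return manifest


def _month_of(doy: np.ndarray) -> np.ndarray:
    from .synthetic import doy_to_month

    return doy_to_month(doy)


def _versions() -> dict:
    from importlib.metadata import version

    out = {}
    for pkg in ("numpy", "scipy", "pandas", "xarray", "click", "pyyaml"):
        try:
            out[pkg] = version(pkg)
        except Exception:
            out[pkg] = "unknown"
    return out
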