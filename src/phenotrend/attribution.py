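"""Environmental and carbon-flux attribution of phenology variability.

Monthly meteorology is aggregated to climatological seasons — spring
(Mar–May), summer (Jun–Aug), autumn (Sep–Nov) and winter (December of the
*previous* year through February) — with mean aggregation for state
variables (TA, TS, VPD, SW_IN, SWC) and sums for precipitation and carbon
fluxes.  A season is missing when any of its months is missing or carries
a QC fraction below 0.75.

Associations are Pearson correlations (pairwise-complete) and partial
correlations (listwise-complete) of annual phenology with seasonal
drivers; partial correlations are computed from the inverse of the
correlation matrix and cross-checked against the recursive elimination
formula.  Site-census helpers classify per-site trends by slope sign and
significance, and compare the prevalence of seasonal carbon-flux trends
between sites with and without significant phenology trends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SEASON_MONTHS",
    "SUM_VARIABLES",
    "AssociationResult",
    "seasonal_aggregate",
    "correlate",
    "partial_correlation",
    "partial_correlation_recursive",
    "significance_census",
    "flux_trend_proportions",
]

SEASON_MONTHS = {
    "spring": (3, 4, 5),
    "summer": (6, 7, 8),
    "autumn": (9, 10, 11),
    "winter": (12, 1, 2),   # Dec belongs to the *previous* calendar year
}

#: Variables aggregated by summation; all others by averaging.
SUM_VARIABLES = frozenset({"P", "GPP", "NEE", "ER"})


@dataclass
class AssociationResult:
    """Correlation of a phenophase with one seasonal driver at one site."""

    site: str
    phenophase: str
    variable: str
    season: str
    r: float = np.nan
    r_partial: float = np.nan
    p: float = np.nan
    n: int = 0
    valid: bool = True


def seasonal_aggregate(
    monthly: pd.DataFrame,
    variable: str,
    season: str,
    qc_threshold: float = 0.75,
) -> pd.Series:
    """Aggregate one monthly variable to an annual seasonal series.

    Winter of year Y spans Dec(Y-1)–Feb(Y).  The value for a year is
    missing when any contributing month is absent, non-finite, or has a QC
    fraction below ``qc_threshold``.
    """
    if season not in SEASON_MONTHS:
        raise ValueError(f"unknown season {season!r}")
    if variable not in monthly.columns:
        raise ValueError(f"variable {variable!r} not in monthly data")
    months = SEASON_MONTHS[season]
    qc_col = f"{variable}_QC"
    has_qc = qc_col in monthly.columns

    df = monthly[["year", "month", variable] + ([qc_col] if has_qc else [])]
    df = df.copy()
    # label each month with the season-year it contributes to
    df["season_year"] = df["year"] + (df["month"] == 12).astype(int) \
        if season == "winter" else df["year"]
    df = df[df["month"].isin(months)]

    out = {}
    for y, g in df.groupby("season_year"):
        if len(g) != 3 or g[variable].isna().any() or \
                not np.isfinite(g[variable]).all():
            out[int(y)] = np.nan
            continue
        if has_qc and (g[qc_col] < qc_threshold).any():
            out[int(y)] = np.nan
            continue
        agg = g[variable].sum() if variable in SUM_VARIABLES \
            else g[variable].mean()
        out[int(y)] = float(agg)
    return pd.Series(out, name=f"{variable}_{season}").sort_index()


def correlate(pheno: pd.Series, env: pd.Series, site: str = "",
              phenophase: str = "", variable: str = "", season: str = "",
              min_n: int = 5) -> AssociationResult:
    """Pearson correlation of annual phenology with one seasonal driver.

    Years missing on either side are dropped (pairwise-complete); fewer
    than ``min_n`` complete pairs or zero variance flags the result.
    """
    joined = pd.concat([pheno, env], axis=1, join="inner").dropna()
    n = len(joined)
    res = AssociationResult(site=site, phenophase=phenophase,
                            variable=variable, season=season, n=n)
    if n < min_n:
        res.valid = False
        return res
    x = joined.iloc[:, 0].to_numpy(dtype=float)
    y = joined.iloc[:, 1].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        res.valid = False
        return res
    r, p = stats.pearsonr(x, y)
    res.r, res.p = float(r), float(p)
    return res


def _partial_from_precision(R: np.ndarray) -> np.ndarray:
    """Partial-correlation matrix from the inverse correlation matrix."""
    P = np.linalg.inv(R)
    d = np.sqrt(np.diag(P))
    out = -P / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out


def partial_correlation_recursive(R: np.ndarray, i: int, j: int,
                                  controls: list[int]) -> float:
    """Partial correlation r_{ij·controls} by recursive elimination.

    Eliminates one control at a time via
    r_{ij·k} = (r_ij - r_ik r_jk) / sqrt((1 - r_ik²)(1 - r_jk²)).
    Serves as the independent route the matrix-inverse computation must
    match.
    """
    if not controls:
        return float(R[i, j])
    k = controls[-1]
    rest = controls[:-1]
    rij = partial_correlation_recursive(R, i, j, rest)
    rik = partial_correlation_recursive(R, i, k, rest)
    rjk = partial_correlation_recursive(R, j, k, rest)
    denom = np.sqrt((1.0 - rik ** 2) * (1.0 - rjk ** 2))
    if denom == 0:
        return np.nan
    return float((rij - rik * rjk) / denom)


def partial_correlation(
    pheno: pd.Series,
    env: pd.DataFrame,
    site: str = "",
    phenophase: str = "",
) -> list[AssociationResult]:
    """Partial correlation of phenology with each driver, controlling the rest.

    Uses listwise-complete years (all variables observed).  Requires at
    least n_vars + 3 complete years; a singular correlation matrix flags
    every result invalid.  p-values use the t distribution with
    n - n_controls - 2 degrees of freedom.
    """
    if env.shape[1] < 2:
        raise ValueError("need at least two environmental series")
    data = pd.concat([pheno.rename("_pheno"), env], axis=1,
                     join="inner").dropna()
    n, nv = len(data), env.shape[1]
    names = list(env.columns)
    results = [
        AssociationResult(site=site, phenophase=phenophase, variable=c,
                          season="", n=n)
        for c in names
    ]
    if n < nv + 3:
        for r in results:
            r.valid = False
        return results
    X = data.to_numpy(dtype=float)
    if np.any(np.std(X, axis=0) == 0):
        for r in results:
            r.valid = False
        return results
    R = np.corrcoef(X, rowvar=False)
    try:
        partial = _partial_from_precision(R)
    except np.linalg.LinAlgError:
        for r in results:
            r.valid = False
        return results
    dof = n - (nv - 1) - 2   # controls = the other nv-1 drivers
    for idx, res in enumerate(results, start=1):
        rp = float(partial[0, idx])
        res.r_partial = rp
        res.r = float(R[0, idx])
        if dof > 0 and abs(rp) < 1.0:
            t = rp * np.sqrt(dof / (1.0 - rp ** 2))
            res.p = float(2.0 * stats.t.sf(abs(t), dof))
        else:
            res.p = np.nan
    return results


def significance_census(trends: pd.DataFrame,
                        levels: tuple[float, float] = (0.05, 0.1)) -> dict:
    """Count sites by trend direction and significance class.

    ``trends`` needs columns ``slope`` and ``p``.  "advancing" counts
    negative slopes, "delaying" positive slopes; each significance bucket
    p<0.05 and p<0.1 is cumulative (p<0.1 includes p<0.05).  Exactly-zero
    slopes are excluded from both directions and reported separately.
    """
    strict, loose = sorted(levels)
    slope = trends["slope"].to_numpy(dtype=float) if len(trends) else \
        np.array([])
    p = trends["p"].to_numpy(dtype=float) if len(trends) else np.array([])
    out = {}
    for label, mask in (("advancing", slope < 0), ("delaying", slope > 0)):
        out[label] = {
            "all": int(mask.sum()),
            f"p<{loose:g}": int((mask & (p < loose)).sum()),
            f"p<{strict:g}": int((mask & (p < strict)).sum()),
        }
    out["zero_slope"] = int((slope == 0).sum())
    out["n_sites"] = int(slope.size)
    return out


def flux_trend_proportions(
    pheno_trends: pd.DataFrame,
    flux_trends: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Prevalence of seasonal flux trends by phenology-trend status.

    ``pheno_trends``: one row per site with columns (site, p).
    ``flux_trends``: rows (site, variable, p) for the seasonal carbon
    fluxes.  Sites are split by whether their phenology trend is
    significant at ``alpha``; within each group the fraction of sites with
    a significant trend in each flux variable is reported.  Empty groups
    yield NaN proportions.
    """
    sig_sites = set(
        pheno_trends.loc[pheno_trends["p"] < alpha, "site"]
    )
    rows = []
    for variable, g in flux_trends.groupby("variable"):
        g = g.set_index("site")
        for label, members in (
            ("with_pheno_trend",
             [s for s in pheno_trends["site"] if s in sig_sites]),
            ("without_pheno_trend",
             [s for s in pheno_trends["site"] if s not in sig_sites]),
        ):
            members = [s for s in members if s in g.index]
            if not members:
                rows.append({"variable": variable, "group": label,
                             "proportion": np.nan, "n_sites": 0})
                continue
            sig = (g.loc[members, "p"] < alpha).sum()
            rows.append({"variable": variable, "group": label,
                         "proportion": float(sig / len(members)),
                         "n_sites": len(members)})
    return pd.DataFrame(rows)
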