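"""Nonparametric trend analysis: Mann–Kendall test with Theil–Sen slopes.

The Mann–Kendall test statistic S counts concordant minus discordant pairs
of an annual series; its variance carries the standard correction for tied
values, and the normal approximation uses a continuity correction
(z = (S ∓ 1)/√var_S).  tau-b is S normalised by the tie-adjusted number of
pairs.  Slopes are Theil–Sen (median of all pairwise slopes) with the
joint-median intercept median(y - slope·x).

Series can be split at an imposed breakpoint year into a "warming period"
and "hiatus" window (the breakpoint year belongs to both windows), and a
start/end-year sensitivity grid recomputes the post-window trend over a
lattice of candidate windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TrendResult",
    "mann_kendall",
    "theil_sen",
    "trend_test",
    "segmented_trends",
    "breakpoint_sensitivity",
    "significance_class",
]


@dataclass
class TrendResult:
    """Trend-test summary for one annual series over one window."""

    slope: float = np.nan        # units per year
    intercept: float = np.nan
    s: float = np.nan            # Kendall score
    tau_b: float = np.nan
    var_s: float = np.nan
    z: float = np.nan
    p: float = np.nan            # two-sided
    n_used: int = 0
    valid: bool = True
    window: tuple[int, int] | None = None
    extra: dict = field(default_factory=dict)

    @classmethod
    def invalid(cls, window=None) -> "TrendResult":
        return cls(valid=False, window=window)


def _clean(years, values):
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    if years.size != values.size:
        raise ValueError("years and values must have equal length")
    if np.any(np.diff(years) <= 0):
        raise ValueError("years must be strictly increasing")
    good = np.isfinite(values)
    return years[good], values[good]


def mann_kendall(years, values) -> TrendResult:
    """Mann–Kendall trend test on an annual series (missing values dropped).

    Requires >= 4 non-missing values.  An all-tied series returns S = 0,
    tau_b = 0, p = 1.
    """
    x, y = _clean(years, values)
    n = y.size
    if n < 4:
        return TrendResult.invalid()

    diff = np.sign(y[None, :] - y[:, None])
    s = float(np.sum(np.triu(diff, k=1)))

    # tie correction over groups of equal values
    _, counts = np.unique(y, return_counts=True)
    t = counts[counts > 1].astype(float)
    var_s = (n * (n - 1) * (2 * n + 5) - np.sum(t * (t - 1) * (2 * t + 5))) / 18.0

    n0 = n * (n - 1) / 2.0
    n1 = np.sum(t * (t - 1) / 2.0)
    denom = np.sqrt((n0 - n1) * n0)   # no ties in time for annual series
    tau_b = s / denom if denom > 0 else 0.0

    if var_s <= 0 or s == 0:
        z = 0.0
    elif s > 0:
        z = (s - 1.0) / np.sqrt(var_s)
    else:
        z = (s + 1.0) / np.sqrt(var_s)
    p = 1.0 if var_s <= 0 else float(2.0 * stats.norm.sf(abs(z)))
    return TrendResult(s=s, tau_b=float(tau_b), var_s=float(var_s),
                       z=float(z), p=min(p, 1.0), n_used=n)


def theil_sen(years, values) -> tuple[float, float]:
    """Theil–Sen slope and joint-median intercept median(y - slope*x)."""
    x, y = _clean(years, values)
    if np.unique(x).size < 2:
        raise ValueError("need at least two distinct years")
    slope, intercept, _, _ = stats.theilslopes(y, x, method="joint")
    return float(slope), float(intercept)


def trend_test(years, values, window: tuple[int, int] | None = None
               ) -> TrendResult:
    """Mann–Kendall test plus Theil–Sen slope for one series."""
    x, y = _clean(years, values)
    if y.size < 4:
        return TrendResult.invalid(window=window)
    res = mann_kendall(x, y)
    res.slope, res.intercept = theil_sen(x, y)
    res.window = window
    return res


def segmented_trends(years, values, breakpoint: int
                     ) -> tuple[TrendResult, TrendResult]:
    """Trends before and after an imposed breakpoint year.

    Both windows are inclusive of the breakpoint year, mirroring
    overlapping period labels like 1982–1998 / 1998–2014.  A window with
    fewer than 4 usable values is flagged invalid.
    """
    years = np.asarray(years)
    if not (years.min() <= breakpoint <= years.max()):
        raise ValueError("breakpoint outside the series span")
    values = np.asarray(values, dtype=float)
    pre = years <= breakpoint
    post = years >= breakpoint
    pre_res = trend_test(years[pre], values[pre],
                         window=(int(years.min()), int(breakpoint)))
    post_res = trend_test(years[post], values[post],
                          window=(int(breakpoint), int(years.max())))
    return pre_res, post_res


def breakpoint_sensitivity(years, values, starts, ends) -> pd.DataFrame:
    """Trend over every (start, end) candidate window, as a tidy table."""
    years = np.asarray(years)
    values = np.asarray(values, dtype=float)
    span = (years.min(), years.max())
    rows = []
    for s0 in starts:
        for e0 in ends:
            if not (span[0] <= s0 <= e0 <= span[1]):
                raise ValueError(f"window ({s0}, {e0}) outside series span")
            sel = (years >= s0) & (years <= e0)
            res = trend_test(years[sel], values[sel], window=(int(s0), int(e0)))
            rows.append(
                {
                    "start": int(s0), "end": int(e0),
                    "slope": res.slope, "intercept": res.intercept,
                    "p": res.p, "n": res.n_used, "valid": res.valid,
                }
            )
    return pd.DataFrame(rows)


def significance_class(p: float, levels: tuple[float, float] = (0.05, 0.1)
                       ) -> str:
    """Classify a p-value into 'p<0.05', 'p<0.1' or 'ns'."""
    strict, loose = sorted(levels)
    if p < strict:
        return f"p<{strict:g}"
    if p < loose:
        return f"p<{loose:g}"
    return "ns"
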