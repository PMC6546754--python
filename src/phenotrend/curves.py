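"""Double-logistic seasonal NDVI/GPP model and its analytic landmarks.

The annual greenness cycle is modelled as the difference of two logistic
limbs on a 365-day year:

    y(t) = a + b * ( 1/(1 + exp(c*(t - d))) - 1/(1 + exp(e*(t - f))) )

with c < 0, e < 0 and d < f, so that ``a`` is the dormant-season background
value, ``a + b`` the summer plateau, ``d`` the spring mid-green-up date and
``f`` the autumn mid-senescence date (both in day of year).  All phenology
retrieval methods operate on this fitted curve; the closed-form landmark
helpers here are exact for well-separated limbs and serve as oracles for
the grid-based numerical retrievals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "DoubleLogisticFit",
    "seasonal_curve",
    "seasonal_curve_deriv",
    "seasonal_curve_deriv2",
    "CURVATURE_OFFSET",
    "inflection_sos",
    "inflection_eos",
    "second_derivative_landmarks",
    "ratio_crossing_sos",
    "ratio_crossing_eos",
]

#: ln(2 + sqrt(3)) — the half-width, in units of 1/|rate|, between a
#: logistic's inflection and the extrema of its second derivative.
CURVATURE_OFFSET = float(np.log(2.0 + np.sqrt(3.0)))


@dataclass
class DoubleLogisticFit:
    """Fitted parameters of the double-logistic seasonal model.

    Attributes
    ----------
    a : float
        Background (dormant season) value.
    b : float
        Seasonal amplitude; the plateau is ``a + b``.
    c, e : float
        Spring and autumn rate parameters (day⁻¹), both negative.
    d, f : float
        Spring and autumn mid-dates (day of year), ``d < f``.
    rss : float
        Residual sum of squares of the fit.
    valid : bool
        False when the optimiser failed or the invariants are violated.
    """

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float
    rss: float = np.nan
    valid: bool = True

    def __post_init__(self) -> None:
        params = (self.a, self.b, self.c, self.d, self.e, self.f)
        if not all(np.isfinite(p) for p in params):
            raise ValueError("double-logistic parameters must be finite")

    @property
    def params(self) -> tuple[float, float, float, float, float, float]:
        return (self.a, self.b, self.c, self.d, self.e, self.f)

    def __call__(self, t):
        return seasonal_curve(t, *self.params)


def seasonal_curve(t, a, b, c, d, e, f):
    """Evaluate the double-logistic seasonal curve at day-of-year ``t``."""
    for p in (a, b, c, d, e, f):
        if not np.all(np.isfinite(p)):
            raise ValueError("double-logistic parameters must be finite")
    if np.any(np.asarray(b) <= 0):
        raise ValueError("amplitude b must be positive")
    t = np.asarray(t, dtype=float)
    return a + b * (expit(-c * (t - d)) - expit(-e * (t - f)))


def _limb(t, rate, mid):
    """Rising logistic limb L = expit(-rate*(t-mid)) and its t-derivatives."""
    L = expit(-rate * (t - mid))
    d1 = -rate * L * (1.0 - L)
    d2 = rate * rate * L * (1.0 - L) * (1.0 - 2.0 * L)
    return L, d1, d2


def seasonal_curve_deriv(t, a, b, c, d, e, f):
    """First derivative dy/dt of the seasonal curve."""
    t = np.asarray(t, dtype=float)
    _, g1, _ = _limb(t, c, d)
    _, g2, _ = _limb(t, e, f)
    return b * (g1 - g2)


def seasonal_curve_deriv2(t, a, b, c, d, e, f):
    """Second derivative d²y/dt² of the seasonal curve."""
    t = np.asarray(t, dtype=float)
    _, _, h1 = _limb(t, c, d)
    _, _, h2 = _limb(t, e, f)
    return b * (h1 - h2)


def inflection_sos(fit: DoubleLogisticFit) -> float:
    """Spring inflection (fastest green-up) of an isolated rising limb."""
    return fit.d


def inflection_eos(fit: DoubleLogisticFit) -> float:
    """Autumn inflection (fastest senescence) of an isolated falling limb."""
    return fit.f


def second_derivative_landmarks(fit: DoubleLogisticFit) -> dict[str, float]:
    """Closed-form second-derivative extrema of each isolated limb.

    For a single logistic limb with rate r < 0 and mid-date m the second
    derivative has extrema at ``m ± ln(2+√3)/|r|``.  On the rising limb the
    earlier extremum marks green-up onset (SOS) and the later one the onset
    of maturity; mirrored on the falling limb for senescence onset and EOS.
    """
    ds = CURVATURE_OFFSET / abs(fit.c)
    da = CURVATURE_OFFSET / abs(fit.e)
    return {
        "sos": fit.d - ds,
        "maturity": fit.d + ds,
        "senescence": fit.f - da,
        "eos": fit.f + da,
    }


def _logit(r: float) -> float:
    return float(np.log(r / (1.0 - r)))


def ratio_crossing_sos(fit: DoubleLogisticFit, ratio: float) -> float:
    """Day the isolated rising limb crosses ``ratio`` of its amplitude."""
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie strictly between 0 and 1")
    return fit.d - _logit(ratio) / fit.c


def ratio_crossing_eos(fit: DoubleLogisticFit, ratio: float) -> float:
    """Day the isolated falling limb drops to ``ratio`` of its amplitude."""
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie strictly between 0 and 1")
    return fit.f + _logit(ratio) / fit.e
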