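import numpy as np
import pytest

from phenotrend import SimulationConfig
from phenotrend.curves import DoubleLogisticFit


@pytest.fixture
def ref_fit() -> DoubleLogisticFit:
    """Reference seasonal curve with well-separated limbs."""
    return DoubleLogisticFit(a=0.2, b=0.5, c=-0.15, d=120.0, e=-0.12, f=280.0)


@pytest.fixture
def small_config() -> SimulationConfig:
    """A small, fast simulation: 3x3 grid, 10 years, mid-series breakpoint."""
    return SimulationConfig(
        n_years=10, start_year=1990, breakpoint_year=1995,
        n_lat=3, n_lon=3, n_sites=2, site_years=10, seed=42,
    )


@pytest.fixture
def noise_free_config() -> SimulationConfig:
    """Stationary noise-free world: every year's cycle is identical."""
    return SimulationConfig(
        n_years=5, start_year=2000, breakpoint_year=2002,
        n_lat=2, n_lon=5, frac_nonveg=0.0,
        sos_slope_pre=0.0, sos_slope_post=0.0,
        eos_slope_pre=0.0, eos_slope_post=0.0,
        noise_sd_ndvi=0.0, noise_sd_pheno=0.0,
        gap_fraction=0.0, gpp_noise_sd=0.0,
        ta_anomaly_sd=0.0, seed=11,
    )


def brute_force_kendall_s(y: np.ndarray) -> float:
    """O(n^2) double-loop Kendall score."""
    s = 0.0
    n = len(y)
    for i in range(n):
        for j in range(i + 1, n):
            s += np.sign(y[j] - y[i])
    return s


def brute_force_theil_sen(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Explicit enumeration of all pairwise slopes."""
    slopes = [
        (y[j] - y[i]) / (x[j] - x[i])
        for i in range(len(x))
        for j in range(i + 1, len(x))
        if x[j] != x[i]
    ]
    slope = float(np.median(slopes))
    return slope, float(np.median(y - slope * x))
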