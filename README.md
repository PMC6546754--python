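# phenotrend

Tools for studying how the timing of the growing season in northern
ecosystems responds to decadal temperature change. The package extracts
the start and end of the growing season (SOS/EOS, in day of year) from
two kinds of records —

* **satellite greenness**: 15-day NDVI composites on a (time, lat, lon)
  grid, via five retrieval methods built on a double-logistic model of
  the seasonal cycle, and
* **eddy-covariance carbon flux**: daily gross primary productivity
  (GPP), via a Gaussian-smoothed percent-of-maximum threshold —

and then asks whether phenology *trends* differ between a warming period
and a warming hiatus, using segmented nonparametric trend tests, and what
environmental factors the interannual variability tracks, using seasonal
correlation and partial-correlation analysis.

Because multi-decadal satellite archives and flux-network downloads are
impractical to bundle, the package ships a simulator that generates both
data types with exactly known phenology: piecewise-linear SOS/EOS
trajectories with a configurable breakpoint year, observation noise, QC
flags and gaps, and meteorology linearly coupled to phenology. Every
stage of the pipeline is tested against this ground truth.

## The model and statistics

The seasonal NDVI cycle of one pixel-year is modelled as

    y(t) = a + b · [ 1/(1+exp(c·(t−d))) − 1/(1+exp(e·(t−f))) ],
    c < 0, e < 0, d < f

with background `a`, amplitude `b` (plateau `a+b`), spring/autumn rate
parameters `c`, `e` and mid-dates `d`, `f`. The retrieval methods are:

| method | landmark |
|---|---|
| 1 | extrema of y″ per limb: SOS = d − ln(2+√3)/\|c\|, EOS = f + ln(2+√3)/\|e\| |
| 2 | extrema of y′ (fastest green-up / senescence): SOS = d, EOS = f |
| 3 | normalized ratio (y − min)/(max − min) crosses 0.2 |
| 4 | same, ratio 0.5 |
| 5 | fixed NDVI thresholds where the multi-year mean cycle's relative change rate (NDVI(t+1)−NDVI(t))/NDVI(t) is extreme, applied to degree-6 polynomial fits of each year |

Flux phenology: SOS/EOS are the first/last days the Gaussian-smoothed
daily GPP stays above/below 15 % of the multi-year smoothed maximum
(typically 1–2 g C m⁻² day⁻¹), with a 4–30 % sensitivity scan.

Trends: Mann–Kendall test (score S, tie-corrected variance,
continuity-corrected z, tau-b) with Theil–Sen slopes (median of all
pairwise slopes), computed separately for the windows before and after an
imposed breakpoint year (the breakpoint year belongs to both windows),
plus a start/end-year sensitivity grid. Attribution uses Pearson
correlation and partial correlation (inverse-correlation-matrix form) of
phenology against seasonal air/soil temperature, VPD, precipitation,
shortwave radiation and soil moisture, and censuses sites by trend
direction and significance (p < 0.05, p < 0.1).

## Worked example

```python
import numpy as np
from phenotrend import (SimulationConfig, generate_ndvi_grid,
                        extract_grid_phenology, aggregate_hemisphere,
                        segmented_trends)

cfg = SimulationConfig(n_years=33, start_year=1982, breakpoint_year=1998,
                       n_lat=10, n_lon=20, frac_nonveg=0.0,
                       sos_slope_pre=-0.34, sos_slope_post=0.0,
                       noise_sd_pheno=1.0, seed=1)
grid, truth = generate_ndvi_grid(cfg)
pheno = extract_grid_phenology(grid)          # five methods + their mean
hemi = aggregate_hemisphere(pheno)
m = hemi[hemi["method"] == "mean"].sort_values("year")
pre, post = segmented_trends(m["year"].to_numpy(), m["sos"].to_numpy(), 1998)
print(f"pre-1998 SOS slope  {pre.slope:+.3f} d/yr  (p = {pre.p:.4f})")
print(f"post-1998 SOS slope {post.slope:+.3f} d/yr  (p = {post.p:.4f})")
```

prints

```
pre-1998 SOS slope  -0.345 d/yr  (p = 0.0000)
post-1998 SOS slope +0.006 d/yr  (p = 0.3434)
```

The recovered pre-breakpoint slope matches the injected
−0.34 days yr⁻¹ advance and is strongly significant; after the
breakpoint the injected trend is zero and the test correctly finds none.

A full end-to-end run (simulation → extraction → trends → attribution,
with all CSV/NetCDF outputs and a manifest) is available from the CLI:

```bash
phenotrend run --config configs/demo.yaml --out demo_out --seed 0
```

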