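# Demo pipeline: simulate a 20x20-cell NDVI stack over 33 years with the
# reference trend magnitudes and a 1998 breakpoint, plus 10 flux sites,
# then run extraction, segmented trends and attribution end to end.
output_dir: phenotrend_demo
simulate: true
breakpoint_year: 1998
gpp_threshold_frac: 0.15
seed: 0
simulation:
  n_years: 33
  start_year: 1982
  breakpoint_year: 1998
  n_lat: 20
  n_lon: 20
  n_sites: 10
  site_years: 15
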