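# Demo run: small synthetic spring-like trial plus three winter seasons of weather.
seed: 7
alpha: 0.05
simulation:
  n_accessions: 120
  year_span: [1995, 2014]
  mean_years_per_accession: 4.36
  mu: 60.0
  sigma2_g: 1.0
  sigma2_year: 1.0
  sigma2_e: 1.0
  record_outlier_rate: 0.03
  record_outlier_shift: 8.0
  year_cv_inflation: {2005: 12.0}
  traits: [FTS, FTE]
curation:
  sd_multiplier: 3.0
  cv_sd_multiplier: 3.0
  tukey_k: 1.5
weather:
  year_span: [2000, 2002]
  gap_rate: 0.05
  implausible_rate: 0.02
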