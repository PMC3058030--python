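{
  "seed": 7,
  "n_separations": 2,
  "fractions_per_separation": 20,
  "metals": [
    "Mo",
    "Ni"
  ],
  "peaks_per_metal": 2,
  "peak_width_range": [
    2,
    5
  ],
  "baseline_mean": 1.0,
  "baseline_cv": 0.2,
  "peak_fold": 8.0,
  "n_replicates": 2,
  "planted_per_metal": 3,
  "p_hit": 0.8,
  "p_bg": 0.02,
  "n_background_proteins": 12,
  "bg_presence": 0.03,
  "peptide_lambda": 1.5,
  "single_peptide_fraction": 0.05
}
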