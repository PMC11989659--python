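{
  "_comment": "Headline statistics as printed in the source cohort report, used only by the validation report to flag print-vs-recompute discrepancies. Never used as computation output.",
  "onset_mean_adult": 44.3,
  "onset_mean_child": 9.6,
  "n_late_onset": 4,
  "mean_logmar_od": 0.96,
  "mean_logmar_os": 0.91,
  "group_counts": {"A": 5, "B": 6, "C": 7},
  "group_percent": {"A": 27.8, "B": 33.3, "C": 38.9},
  "group_onset_central": {"A": 39.4, "B": 18.5, "C": 10.4},
  "group_bcva_central": {"A": 0.748, "B": 0.878, "C": 1.113},
  "severity_percent": {"1": 26.7, "2": 33.3, "3": 40.0},
  "af_counts": {"1": 4, "2": 6, "3": 4},
  "n_variants_total": 31,
  "n_missense": 11,
  "n_novel": 8,
  "zygosity_percent_biallelic_het": 77.8
}
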