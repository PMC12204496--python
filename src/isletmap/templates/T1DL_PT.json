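{
 "cd45_model": {
  "nb_dispersion": 0.8,
  "nb_mean": 2.0,
  "p_any_cd45": 0.25,
  "p_insulitic": 0.001
 },
 "cell_density_per_mm2": 9000.0,
 "cluster_weights": {
  "I": 0.0,
  "II": 0.005,
  "III": 0.0,
  "IV": 0.005,
  "V-A": 0.19,
  "V-BC": 0.8
 },
 "donor_jitter": 0.1,
 "frac_GCG_deficient": 0.02,
 "frac_IDI": 0.995,
 "frac_PPY_dominant": 0.005,
 "hormone_rules": {
  "I": {
   "CHGA": 0.85,
   "GCG": 0.15,
   "IAPP": 0.3,
   "INS": 0.35,
   "PPY": 0.004,
   "ProGCG": 0.28,
   "ProINS_hi": 0.2,
   "ProINS_total": 0.55,
   "SST": 0.08
  },
  "II": {
   "CHGA": 0.85,
   "GCG": 0.16,
   "IAPP": 0.25,
   "INS": 0.3,
   "PPY": 0.004,
   "ProGCG": 0.3,
   "ProINS_hi": 0.15,
   "ProINS_total": 0.45,
   "SST": 0.08
  },
  "III": {
   "CHGA": 0.6,
   "GCG": 0.004,
   "IAPP": 0.25,
   "INS": 0.3,
   "PPY": 0.35,
   "ProGCG": 0.004,
   "ProINS_hi": 0.15,
   "ProINS_total": 0.45,
   "SST": 0.08
  },
  "IV": {
   "CHGA": 0.3,
   "GCG": 0.004,
   "IAPP": 0.004,
   "INS": 0.004,
   "PPY": 0.85,
   "ProGCG": 0.004,
   "ProINS_hi": 0.002,
   "ProINS_total": 0.004,
   "SST": 0.06
  },
  "V-A": {
   "CHGA": 0.8,
   "GCG": 0.28,
   "IAPP": 0.004,
   "INS": 0.004,
   "PPY": 0.004,
   "ProGCG": 0.55,
   "ProINS_hi": 0.002,
   "ProINS_total": 0.004,
   "SST": 0.12
  },
  "V-BC": {
   "CHGA": 0.8,
   "GCG": 0.25,
   "IAPP": 0.004,
   "INS": 0.004,
   "PPY": 0.004,
   "ProGCG": 0.5,
   "ProINS_hi": 0.002,
   "ProINS_total": 0.004,
   "SST": 0.14
  }
 },
 "islet_density_per_mm2": 1.0,
 "pancreas_region_weight_g": 20.0,
 "region": "PT",
 "size_log_mu": 7.7731018951944515,
 "size_log_sigma": 0.85,
 "spatial_mode": "thinned_patches",
 "stage_label": "T1DL"
}
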