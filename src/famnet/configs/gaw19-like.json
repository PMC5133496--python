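{
  "family_sizes": [65, 55, 45, 62, 49],
  "n_probes": 2000,
  "modules": [
    {"size": 100, "loading": 0.8, "shared": true},
    {"size": 90, "loading": 0.8, "shared": true},
    {"size": 80, "loading": 0.7, "shared": true},
    {"size": 70, "loading": 0.7, "shared": true},
    {"size": 60, "loading": 0.8, "shared": false, "home_family": 0},
    {"size": 50, "loading": 0.8, "shared": false, "home_family": 3}
  ],
  "sigma_g2": 0.4,
  "sigma_v2": 0.2,
  "sigma_e2": 1.0,
  "n_causal": 15,
  "causal_effect": 0.3,
  "trait_polygenic_var": 1.0,
  "trait_noise_var": 1.0,
  "age_range": [20.0, 80.0],
  "expr_age_effect": 0.005,
  "expr_sex_effect": 0.1,
  "trait_age_effect": 0.2,
  "trait_sex_effect": 2.0,
  "seed": 1
}
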