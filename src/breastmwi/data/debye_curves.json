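{
  "version": "1.0",
  "notes": "Single-pole Debye parameters (eps_inf, delta_eps, tau in seconds, sigma_s in S/m) of the tissue dielectric-property curves, valid 3-10 GHz. 'tumour_percentiles' holds the Debye fits of the malignant-tumour 25th/75th-percentile Cole-Cole curves.",
  "curves": {
    "Minimum":               {"eps_inf": 2.309, "delta_eps": 0.092, "tau": 13.0e-12, "sigma_s": 0.005},
    "Fibroglandular_low":    {"eps_inf": 12.99, "delta_eps": 24.40, "tau": 13.0e-12, "sigma_s": 0.397},
    "Fibroglandular_median": {"eps_inf": 13.81, "delta_eps": 35.55, "tau": 13.0e-12, "sigma_s": 0.738},
    "Fibroglandular_high":   {"eps_inf": 14.20, "delta_eps": 40.49, "tau": 13.0e-12, "sigma_s": 0.824},
    "Fat_low":               {"eps_inf": 2.848, "delta_eps": 1.104, "tau": 13.0e-12, "sigma_s": 0.005},
    "Fat_median":            {"eps_inf": 3.116, "delta_eps": 1.592, "tau": 13.0e-12, "sigma_s": 0.050},
    "Fat_high":              {"eps_inf": 3.987, "delta_eps": 3.545, "tau": 13.0e-12, "sigma_s": 0.080},
    "Maximum":               {"eps_inf": 23.20, "delta_eps": 46.05, "tau": 13.0e-12, "sigma_s": 1.306},
    "Skin":                  {"eps_inf": 15.93, "delta_eps": 23.83, "tau": 13.0e-12, "sigma_s": 0.831},
    "Muscle":                {"eps_inf": 21.66, "delta_eps": 33.24, "tau": 13.0e-12, "sigma_s": 0.886}
  },
  "tumour_percentiles": {
    "25th": {"eps_inf": 12.9, "delta_eps": 33.9, "tau": 13.0e-12, "sigma_s": 1.38},
    "75th": {"eps_inf": 14.6, "delta_eps": 47.2, "tau": 13.0e-12, "sigma_s": 1.60}
  }
}
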