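{
  "version": 1,
  "unit": "cm^-1",
  "comment": "Optical properties of human vertebral bone at the two probe wavelengths and the default optoelectronic channel parameters of the handheld probe.",
  "tissues": {
    "cancellous": {
      "940": {"mu_a": 0.216, "mu_s_prime": 28.6, "g": 0.9},
      "1310": {"mu_a": 0.833, "mu_s_prime": 17.3, "g": 0.9}
    },
    "cortical": {
      "940": {"mu_a": 0.223, "mu_s_prime": 16.4, "g": 0.9},
      "1310": {"mu_a": 0.920, "mu_s_prime": 11.3, "g": 0.9}
    }
  },
  "channels": {
    "940": {
      "p_ld_mw": 51.1,
      "eta_ld": 0.30,
      "eta_pd": 0.30,
      "r_pd_a_per_w": 0.62,
      "r_tissue_permille": {"cancellous": 0.152, "cortical": 0.149}
    },
    "1310": {
      "p_ld_mw": 10.3,
      "eta_ld": 0.30,
      "eta_pd": 0.30,
      "r_pd_a_per_w": 0.91,
      "r_tissue_permille": {"cancellous": 0.120, "cortical": 0.0955}
    }
  },
  "photodiode": {
    "junction_capacitance_pf": 60,
    "peak_responsivity_a_per_w": 1.05,
    "peak_responsivity_nm": 1550,
    "spectral_range_nm": [500, 1700]
  }
}
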