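{
  "4":  {"mean_MeV": 1.52, "dose_per_photon_Gy": 6.031e-14, "dose_per_photon_sigma_Gy": 0.058e-14, "max_MeV": 4.0},
  "6":  {"mean_MeV": 1.79, "dose_per_photon_Gy": 6.497e-14, "dose_per_photon_sigma_Gy": 0.025e-14, "max_MeV": 6.0},
  "6E": {"mean_MeV": 2.01, "dose_per_photon_Gy": 7.403e-14, "dose_per_photon_sigma_Gy": 0.025e-14, "max_MeV": 6.0},
  "10": {"mean_MeV": 3.20, "dose_per_photon_Gy": 1.028e-13, "dose_per_photon_sigma_Gy": 0.036e-13, "max_MeV": 10.0},
  "15": {"mean_MeV": 3.88, "dose_per_photon_Gy": 1.066e-13, "dose_per_photon_sigma_Gy": 0.045e-13, "max_MeV": 15.0},
  "18": {"mean_MeV": 4.89, "dose_per_photon_Gy": 1.288e-13, "dose_per_photon_sigma_Gy": 0.056e-13, "max_MeV": 18.0}
}
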