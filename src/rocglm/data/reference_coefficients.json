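{
  "description": "ROC regression coefficients reported by the motivating clinical case-control study (173 glaucomatous / 63 unaffected eyes) for three Cirrus HD-OCT thickness markers, with the covariate profiles at which the published covariate-specific AUROCs were evaluated.",
  "age_sign_note": "The published point estimate of the average-RNFL age coefficient (0.0160) contradicts both its own 95% CI (-0.0311, -0.0009) and the accompanying text; it is stored here as -0.0160, the sign-harmonised value.",
  "covariate_units": {
    "vfi": "percent",
    "age": "years",
    "spherical_equivalent": "diopters",
    "axial_length": "mm",
    "corrected_disc_area": "mm^2"
  },
  "baseline_profile": {
    "age": 55.0,
    "spherical_equivalent": -2.15,
    "axial_length": 24.5,
    "corrected_disc_area": 2.0
  },
  "severity_grid_vfi": [100.0, 90.0, 80.0, 70.0],
  "geometry_series_vfi": 92.0,
  "axial_length_grid": [23.0, 24.5, 26.0],
  "disc_area_grid": [1.5, 2.0, 2.5],
  "markers": {
    "rnfl_avg": {
      "alpha1": 3.3567,
      "alpha2": 0.9892,
      "betas": {
        "vfi": -0.0478,
        "age": -0.0160,
        "spherical_equivalent": 0.0089,
        "axial_length": 0.1848,
        "corrected_disc_area": -0.4723
      }
    },
    "gcipl_avg": {
      "alpha1": -0.1257,
      "alpha2": 1.7437,
      "betas": {
        "vfi": -0.0451,
        "age": 0.0122,
        "spherical_equivalent": 0.009,
        "axial_length": 0.1866,
        "corrected_disc_area": 0.0104
      }
    },
    "gcipl_min": {
      "alpha1": 8.0907,
      "alpha2": 0.701,
      "betas": {
        "vfi": -0.0578,
        "age": 0.0118,
        "spherical_equivalent": -0.0178,
        "axial_length": -0.0783,
        "corrected_disc_area": -0.003
      }
    }
  }
}
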