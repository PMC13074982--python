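{
  "comment": "Published MLR equations for aqueous adsorption energies (kcal/mol) of organic compounds on microplastics. 'split43' models were fitted on a 43-compound training set with descriptors ATSC1m, AATSC0v, MATS1m, BCUTw-1h; 'full54' models on all 54 compounds with AATS1m, AATS7p, ATSC0p, AATSC1p. Coefficients are the printed values, stored verbatim.",
  "split43": {
    "descriptors": ["ATSC1m", "AATSC0v", "MATS1m", "BCUTw-1h"],
    "n": 43,
    "PE":  {"intercept": 9.879,  "coefficients": [-0.039, -0.212, -21.91, -0.638],
            "stats": {"R2": 0.98, "RMSE_t": 2.44, "Q2_LOO": 0.98, "F": 569.27,
                      "n_v": 11, "R2_ext": 0.92, "Q2_ext": 0.85, "RMSE_v": 7.82}},
    "POM": {"intercept": 10.889, "coefficients": [-0.04, -0.217, -3.728, -0.482],
            "stats": {"R2": 0.96, "RMSE_t": 3.11, "Q2_LOO": 0.94, "F": 212.516,
                      "n_v": 11, "R2_ext": 0.88, "Q2_ext": 0.81, "RMSE_v": 6.59}},
    "PVA": {"intercept": 10.709, "coefficients": [-0.047, -0.157, -6.006, -0.661],
            "stats": {"R2": 0.96, "RMSE_t": 3.96, "Q2_LOO": 0.94, "F": 217.305,
                      "n_v": 11, "R2_ext": 0.90, "Q2_ext": 0.85, "RMSE_v": 7.88}}
  },
  "full54": {
    "descriptors": ["AATS1m", "AATS7p", "ATSC0p", "AATSC1p"],
    "n": 54,
    "PE":  {"intercept": 11.520, "coefficients": [-0.090, 6.934, -4.129, 28.365],
            "stats": {"R2": 0.96, "Q2_LOO": 0.95, "RMSE": 3.91, "F": 285.277}},
    "POM": {"intercept": 9.285,  "coefficients": [-0.068, 6.050, -3.229, 31.582],
            "stats": {"R2": 0.95, "Q2_LOO": 0.93, "RMSE": 3.47, "F": 220.548}},
    "PVA": {"intercept": 14.772, "coefficients": [-0.097, 6.944, -3.987, 36.499],
            "stats": {"R2": 0.94, "Q2_LOO": 0.92, "RMSE": 4.81, "F": 190.469}}
  },
  "y_randomization_mean_R2": {"split43": {"PE": 0.12, "POM": 0.10, "PVA": 0.07},
                               "full54": {"PE": 0.09, "POM": 0.09, "PVA": 0.05}}
}
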