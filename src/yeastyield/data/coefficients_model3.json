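{
  "format": "yeastyield-coefficients/1",
  "variant": "model3",
  "coefficients": {
    "Intercept": -1.73,
    "PRI": 0.003,
    "SEC": -0.19,
    "OVE_C2": 0.05,
    "OVE_C3": 0.56,
    "KNO_C2": 0.37,
    "NUT_C2": 0.71,
    "INT_C2": 0.86,
    "CUL_C2": 0.51,
    "OXY_C2": 0.12
  },
  "std_errors": {
    "Intercept": 0.41,
    "PRI": 0.03,
    "SEC": 0.02,
    "OVE_C2": 0.24,
    "OVE_C3": 0.28,
    "KNO_C2": 0.17,
    "NUT_C2": 0.17,
    "INT_C2": 0.29,
    "CUL_C2": 0.21,
    "OXY_C2": 0.27
  },
  "t_stats": {},
  "p_values": {
    "Intercept": 0.0,
    "PRI": 0.93,
    "SEC": 0.0,
    "OVE_C2": 0.84,
    "OVE_C3": 0.05,
    "KNO_C2": 0.03,
    "NUT_C2": 0.0,
    "INT_C2": 0.004,
    "CUL_C2": 0.02,
    "OXY_C2": 0.65
  },
  "r_squared": 0.58,
  "n_obs": null,
  "df_resid": null,
  "source": "published"
}
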