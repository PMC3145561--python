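{
  "format": "yeastyield-coefficients/1",
  "variant": "model1",
  "coefficients": {
    "Intercept": -1.53,
    "PRI": -0.01,
    "SEC": -0.19,
    "OVE_C2": 0.007,
    "OVE_C3": 0.52,
    "KNO_C2": 0.31,
    "NUT_C2": 0.73,
    "INT_C2": 0.77,
    "CUL_C2": 0.51,
    "OXY_C2": 0.27
  },
  "std_errors": {
    "Intercept": 0.42,
    "PRI": 0.04,
    "SEC": 0.02,
    "OVE_C2": 0.26,
    "OVE_C3": 0.29,
    "KNO_C2": 0.18,
    "NUT_C2": 0.18,
    "INT_C2": 0.31,
    "CUL_C2": 0.22,
    "OXY_C2": 0.27
  },
  "t_stats": {},
  "p_values": {
    "Intercept": 0.0,
    "PRI": 0.76,
    "SEC": 0.0,
    "OVE_C2": 0.98,
    "OVE_C3": 0.07,
    "KNO_C2": 0.08,
    "NUT_C2": 0.0,
    "INT_C2": 0.02,
    "CUL_C2": 0.02,
    "OXY_C2": 0.32
  },
  "r_squared": 0.55,
  "n_obs": null,
  "df_resid": null,
  "source": "published"
}
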