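{
  "format": "yeastyield-coefficients/1",
  "variant": "model2",
  "coefficients": {
    "Intercept": -1.6,
    "SEC": -0.19,
    "OVE_C2": 0.0003,
    "OVE_C3": 0.5,
    "KNO_C2": 0.31,
    "NUT_C2": 0.73,
    "INT_C2": 0.82,
    "CUL_C2": 0.51,
    "OXY_C2": 0.28
  },
  "std_errors": {
    "Intercept": 0.34,
    "SEC": 0.02,
    "OVE_C2": 0.25,
    "OVE_C3": 0.28,
    "KNO_C2": 0.18,
    "NUT_C2": 0.18,
    "INT_C2": 0.25,
    "CUL_C2": 0.21,
    "OXY_C2": 0.27
  },
  "t_stats": {},
  "p_values": {
    "Intercept": 0.0,
    "SEC": 0.0,
    "OVE_C2": 0.99,
    "OVE_C3": 0.079,
    "KNO_C2": 0.078,
    "NUT_C2": 0.0,
    "INT_C2": 0.001,
    "CUL_C2": 0.02,
    "OXY_C2": 0.31
  },
  "r_squared": 0.55,
  "n_obs": null,
  "df_resid": null,
  "source": "published"
}
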