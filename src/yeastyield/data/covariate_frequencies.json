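{
  "description": "Empirical covariate frequencies of the packaged training corpus; measured once and stored so simulation defaults do not drift with fixture edits.",
  "ove_freqs": {
    "C1": 0.1508,
    "C2": 0.4921,
    "C3": 0.3571
  },
  "binary_freqs": {
    "KNO": 0.4524,
    "NUT": 0.3175,
    "INT": 0.127,
    "CUL": 0.254,
    "OXY": 0.127
  },
  "pri_dist": {
    "1": 2,
    "2": 1,
    "3": 1,
    "4": 21,
    "5": 18,
    "6": 2,
    "8": 6,
    "9": 20,
    "10": 37,
    "11": 1,
    "12": 16,
    "13": 1
  },
  "sec_dist": {
    "0": 3,
    "1": 5,
    "1.5": 3,
    "2": 38,
    "3": 15,
    "4": 1,
    "5": 2,
    "6": 2,
    "7": 4,
    "8": 6,
    "8.5": 2,
    "9": 17,
    "9.5": 1,
    "10": 11,
    "10.5": 4,
    "11": 2,
    "12": 1,
    "14": 7,
    "21": 2
  },
  "calibrated_noise_sd": 0.88
}
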