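{
  "description": "SYNTHETIC normative table for demonstration and testing only. Strata means/sds are fabricated round numbers, not published population norms; real deployments must supply their own normative file in the same format.",
  "instruments": {
    "MoCA": {
      "min": 0,
      "max": 30,
      "strata": [
        {"criteria": {"age": [18, 49], "education": [0, 9]}, "mean": 25.0, "sd": 3.0},
        {"criteria": {"age": [18, 49], "education": [10, 25]}, "mean": 27.0, "sd": 2.5},
        {"criteria": {"age": [50, 69], "education": [0, 9]}, "mean": 23.0, "sd": 3.5},
        {"criteria": {"age": [50, 69], "education": [10, 25]}, "mean": 25.5, "sd": 3.0},
        {"criteria": {"age": [70, 110], "education": [0, 9]}, "mean": 21.0, "sd": 4.0},
        {"criteria": {"age": [70, 110], "education": [10, 25]}, "mean": 24.0, "sd": 3.5}
      ]
    },
    "FCSRT": {
      "min": 0,
      "max": 48,
      "strata": [
        {"criteria": {"age": [18, 69]}, "mean": 32.0, "sd": 6.0},
        {"criteria": {"age": [70, 110]}, "mean": 28.0, "sd": 7.0}
      ]
    },
    "WAISIII": {
      "min": 0,
      "max": 133,
      "strata": [
        {"criteria": {"age": [18, 69]}, "mean": 70.0, "sd": 15.0},
        {"criteria": {"age": [70, 110]}, "mean": 55.0, "sd": 16.0}
      ]
    },
    "ToulousePieron": {
      "min": 0,
      "max": 37.5,
      "strata": [
        {"criteria": {"age": [18, 69]}, "mean": 22.0, "sd": 6.0},
        {"criteria": {"age": [70, 110]}, "mean": 17.0, "sd": 6.5}
      ]
    }
  }
}
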