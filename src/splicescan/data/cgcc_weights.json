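{
  "description": "Run-length weights for the cGcC (consecutive G over consecutive C) score. A maximal run of n identical G (or C) bases contributes run_weights[n]; runs longer than the table extrapolate as unit * n^2 (each base in a run of length n weighs unit * n). Edit this file, not code, to correct the scheme.",
  "unit": 10,
  "run_weights": {
    "1": 10,
    "2": 40,
    "3": 90,
    "4": 160,
    "5": 250,
    "6": 360,
    "7": 490,
    "8": 640,
    "9": 810,
    "10": 1000,
    "11": 1210,
    "12": 1440
  },
  "extrapolation": "quadratic"
}
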