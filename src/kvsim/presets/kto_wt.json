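{
  "kind": "Kto",
  "x1": 27.4, "x2": 42.6, "x3": 42.5, "x4": 7.0,
  "x5": 33.5, "x6": 55.7, "x7": 36.0,
  "Gto": 0.193,
  "fixed": ["x4", "x5"]
}
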