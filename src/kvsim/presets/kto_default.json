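{
  "kind": "Kto",
  "x1": 30.0, "x2": 30.0, "x3": 13.5, "x4": 7.0,
  "x5": 33.5, "x6": 33.5, "x7": 7.0,
  "Gto": 0.4067,
  "fixed": ["x4", "x5"]
}
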