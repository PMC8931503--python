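{
  "kind": "Kslow",
  "x1": 22.5, "x2": 7.7, "x3": 45.2, "x4": 5.7,
  "x5": 2.058, "x6": 1200.0, "x7": 45.2, "x8": 5.7,
  "Gr": 0.16,
  "fixed": ["x5", "x7", "x8"]
}
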