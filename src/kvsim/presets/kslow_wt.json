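{
  "kind": "Kslow",
  "x1": 33.2, "x2": 7.6, "x3": 54.3, "x4": 12.4,
  "x5": 2.058, "x6": 1432.4, "x7": 45.2, "x8": 5.7,
  "Gr": 0.153,
  "fixed": ["x5", "x7", "x8"]
}
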