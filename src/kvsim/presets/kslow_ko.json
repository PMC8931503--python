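{
  "kind": "Kslow",
  "x1": 18.0, "x2": 10.7, "x3": 56.4, "x4": 10.6,
  "x5": 2.058, "x6": 1853.9, "x7": 45.2, "x8": 5.7,
  "Gr": 0.075,
  "fixed": ["x5", "x7", "x8"]
}
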