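{
 "counts": {
  "111": 69,
  "110": 19,
  "101": 7,
  "100": 12,
  "011": 32,
  "010": 9,
  "001": 5,
  "000": 51
 },
 "labels": ["SSDC", "ISDS", "ESD"]
}
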