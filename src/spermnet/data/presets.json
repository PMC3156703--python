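{
 "dK": {
  "dK": 0
 },
 "LVA": {
  "LVA": 0
 },
 "PDE": {
  "PDE": 0
 },
 "CaCC": {
  "CaCC": 0
 },
 "CaKC": {
  "CaKC": 0
 },
 "HVA": {
  "HVA": 0
 }
}
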