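{
  "pyrene": 202.25,
  "2,2'-diphenic acid": 242.23,
  "1-hydroxy-2-naphthoic acid": 188.18,
  "phthalic acid": 166.13,
  "salicylic acid": 138.12,
  "protocatechuic acid": 154.12,
  "fluorene": 166.22,
  "phenanthrene": 178.23
}
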