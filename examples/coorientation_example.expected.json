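{
  "k": 15,
  "seed": 7,
  "gi": 3.3287500000000003,
  "li": 0.9112499999999999,
  "n": 800
}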