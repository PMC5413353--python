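{
  "interaction": {
    "kind": "proportional",
    "value": 0.3
  },
  "model": "orientation",
  "mu": 0.0,
  "n": 800,
  "seed": 42,
  "sigma_x": 25.0,
  "sigma_y": 25.0
}
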