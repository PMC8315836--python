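{
  "epsilon": 0.27,
  "mg1": 0.32,
  "mg_inf": 0.45,
  "sg1": 0.27,
  "sg_inf": 0.42,
  "alpha1": 0.12,
  "alpha_inf": 0.17,
  "d0": -0.67,
  "beta_minus": 0.14,
  "beta_plus": 0.11
}
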