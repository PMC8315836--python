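{
  "epsilon": 0.39,
  "mg1": 0.41,
  "mg_inf": 0.55,
  "sg1": 0.32,
  "sg_inf": 0.37,
  "alpha1": 0.22,
  "alpha_inf": 0.36,
  "d0": -0.12,
  "beta_minus": 0.09,
  "beta_plus": 0.13
}
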