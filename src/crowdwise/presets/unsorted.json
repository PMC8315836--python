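{
  "epsilon": 0.21,
  "mg1": 0.41,
  "mg_inf": 0.38,
  "sg1": 0.33,
  "sg_inf": 0.43,
  "alpha1": 0.20,
  "alpha_inf": 0.16,
  "d0": 0.04,
  "beta_minus": 0.04,
  "beta_plus": 0.16
}
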