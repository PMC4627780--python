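model,kPG,se_kPG,kRp,se_kRp,kS,se_kS,rank,gamma,kappa,residual
Lung 1,0.005,0.154,23.7,84.9,0.07,0.05,3,85,16122,0.04
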