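model,kp,se_kp,kRp,se_kRp,dV,kappa,gamma,rank,residual
Calu3,0.0001,0.0014,0.90,64.90,0.0007,10,11,2,<0.01
Lung 1,0.0003,0.0021,5.38,71.27,0.0005,6,1,2,0.10
Lung 2,0.0001,0.0003,4.78,2.45,0.0008,12,42,2,0.01
Colon 1,0.0007,0.0023,7.86,38.37,8.711,7,8,2,0.04
Colon 2,0.0001,0.0009,1.88,54.24,0.0096,9,3,2,0.03
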