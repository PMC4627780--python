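parameter,units,Ribba2010,MCF7
kp,(mmHg x day)^-1,0.0058,0.0027
SE(kp),(mmHg x day)^-1,0.0041,0.0027
kRp,cm^-1,13.37,7.54
SE(kRp),cm^-1,2.39,1.90
KH,mmHg,25.9,13.8
SE(KH),mmHg,54.0,27.3
KN,mmHg,20.2,-
SE(KN),mmHg,3.8,-
Rank,-,312,342
Y,-,49,35
k,-,4,3
Residual,-,0.18,0.09
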