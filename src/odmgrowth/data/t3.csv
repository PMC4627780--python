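system,tissue,cell_line,flag,kp,se_kp,kRp,se_kRp,dV,kappa,gamma,rank,residual
Repr. Sys.,Lung,Calu6,*,0.0001,0.0018,5.06,<0.01,0.10,529500,17874,2,0.20
Repr. Sys.,Colon,Colo205,,0.0005,0.0014,3.17,2.24,0.03,46,9,2,0.10
Repr. Sys.,Lung,H460,,0.0041,0.0035,13.38,3.08,0.14,135,10,2,0.30
Repr. Sys.,Lung,H1975,#,0.0013,0.0020,6.05,2.21,0.05,43,21,2,0.06
Repr. Sys.,Lung,H3255,,0.0001,0.0012,2.83,17.08,0.03,6,3,2,0.02
Repr. Sys.,Lung,A2058,,0.0005,0.0030,6.26,16.02,0.07,8,4,2,0.07
Repr. Sys.,Lung,PC9,,0.0003,0.0008,8.23,41.11,0.03,3,1,2,0.15
Repr. Sys.,Lung,A549b,,0.0001,0.0026,3.22,22.90,0.06,11,2,2,0.03
Repr. Sys.,Breast,HCC1954,#,0.00005,0.0004,1.40,2.40,0.06,19,15,2,0.01
Repr. Sys.,Cervix,ME180,#,0.0003,0.0014,3.20,3.39,0.03,14,21,2,0.02
Gastrointestinal,Gastric,SNU5,#,0.0004,0.0011,3.35,2.32,0.04,56,17,2,0.04
Gastrointestinal,Gastric,SGC31,,0.0002,0.0015,6.59,34.59,0.05,8,4,2,0.03
Gastrointestinal,Gastric,SGC37,,0.0005,0.0031,8.51,46.99,0.01,9,1,2,0.15
Gastrointestinal,Gastric,SGC70,,0.0008,0.0045,11.64,28.99,0.05,13,2,2,0.21
Gastrointestinal,Gastric,SGC71,,0.0005,0.0043,7.46,29.73,0.08,11,2,2,0.08
Gastrointestinal,Gastric,SGC100,,0.0002,0.0041,3.06,53.31,0.08,7,1,2,0.02
Gastrointestinal,Gastric,SGC161,#,0.0005,0.0016,3.33,2.63,0.04,31,28,2,0.02
Gastrointestinal,Gastric,SGC181,#,0.0005,0.0019,2.69,2.58,0.03,35,32,2,0.01
Gastrointestinal,Gastric,SGC184,#,0.0002,0.0028,4.22,5.70,0.03,89,19,2,0.03
Gastrointestinal,Gastric,MKN45,#,0.0006,0.0013,4.03,2.49,0.05,64,18,2,0.03
Gastrointestinal,Gastric,HS746T,,0.0007,0.0050,9.68,36.93,0.04,9,1,2,0.15
Gastrointestinal,Colon,MC38,#,0.0043,0.0047,17.19,3.94,0.13,93,15,2,0.11
Gastrointestinal,Colon,Lovo,,0.0009,0.0040,14.87,26.75,0.24,10,2,2,0.23
Gastrointestinal,Colon,HCT116,,0.0002,0.0029,4.93,40.20,0.11,10,1,2,0.07
Gastrointestinal,Colon,HT29,#,0.0011,0.0021,4.30,2.23,0.06,84,16,2,0.04
Other,Skin,A375,#,0.0022,0.0018,11.71,2.88,0.06,139,12,2,0.19
Other,Bladder,MGHU3,#,0.0035,0.0036,7.81,1.99,0.09,77,12,2,0.26
Other,Kidney,RCC47,,0.0002,0.0003,6.85,3.47,0.00,4,11,2,0.51
Other,Kidney,786O,#,0.0004,0.0007,4.68,2.31,-0.01,33,14,2,0.06
Other,Blood,KMS11,,0.0002,0.0022,5.85,35.80,0.07,11,1,2,0.08
Other,Lymph,HT1080,,0.0030,0.0028,8.52,1.98,0.07,78,10,2,0.36
Other,Lymph,Ri1,,0.0002,0.0027,3.32,34.28,0.07,6,1,2,0.06
Other,Lymph,RS411,,0.0003,0.0024,12.42,25.71,0.12,16,2,2,0.18
Other,Lymph,OCLy10,*,>100,-,>100,-,0.03,>10000,>1000,2,0.04
Other,Lymph,OCLy19,,0.0002,0.0044,4.17,25.02,0.12,17,2,2,0.04
Other,Lymph,A20,,0.0003,0.0004,7.31,2.55,0.01,14,5,2,0.57
Other,Mouse,CT26,,0.0003,0.0032,3.07,33.56,0.03,9,2,2,0.09
Other,Stem cell,ECB1,,0.0001,0.0011,1.63,27.49,0.04,4,1,2,0.04
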