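salt,MS,1/2MSM,1/4MSM,1/8MSM,0MSM,1/2MSμ,1/4MSμ,1/8MSμ,0MSμ
KNO3,1900,950,475,237.5,0,1900,1900,1900,1900
NH4NO3,1650,825,412.5,206.3,0,1650,1650,1650,1650
CaCl2.2H2O,440,220,110,55,0,440,440,440,440
MgSO4.7H2O,370,185,92.5,46.3,0,370,370,370,370
KH2PO4,170,85,42.5,21.3,0,170,170,170,170
MnSO4.4H2O,22.3,22.3,22.3,22.3,22.3,11.2,5.6,2.8,0
ZnSO4.7H2O,8.6,8.6,8.6,8.6,8.6,4.3,2.2,1.1,0
H3BO3,6.2,6.2,6.2,6.2,6.2,3.1,1.6,0.78,0
KI,0.83,0.83,0.83,0.83,0.83,0.42,0.21,0.10,0
Na2MoO4.2H2O,0.25,0.25,0.25,0.25,0.25,0.13,0.063,0.031,0
CuSO4.5H2O,0.025,0.025,0.025,0.025,0.025,0.013,0.0063,0.0031,0
CoCl2.6H2O,0.025,0.025,0.025,0.025,0.025,0.013,0.0063,0.0031,0
Na2EDTA,37.25,37.25,37.25,37.25,37.25,37.25,37.25,37.25,37.25
FeSO4.7H2O,27.85,27.85,27.85,27.85,27.85,27.85,27.85,27.85,27.85
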