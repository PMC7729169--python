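salt,molar_mass,ions
KNO3,101.10,K+:1;NO3-:1
NH4NO3,80.04,NH4+:1;NO3-:1
CaCl2.2H2O,147.01,Ca2+:1;Cl-:2
MgSO4.7H2O,246.47,Mg2+:1;SO42-:1
KH2PO4,136.09,K+:1;H2PO4-:1
MnSO4.4H2O,223.06,Mn2+:1;SO42-:1
ZnSO4.7H2O,287.56,Zn2+:1;SO42-:1
H3BO3,61.83,BO33-:1
KI,166.00,K+:1;I-:1
Na2MoO4.2H2O,241.95,Na+:2;MoO42-:1
CuSO4.5H2O,249.69,Cu2+:1;SO42-:1
CoCl2.6H2O,237.93,Co2+:1;Cl-:2
Na2EDTA,336.21,Na+:2;EDTA:1
FeSO4.7H2O,278.01,Fe2+:1;SO42-:1
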