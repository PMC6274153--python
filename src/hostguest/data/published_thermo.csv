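label,method,n,ka_per_M,dh_kcal_mol,dg_kcal_mol,tds_kcal_mol,temperature_K
CT@CB7,itc,0.99,1.44e4,-13.23,-5.69,-7.57,298.15
CT@CB7,nmr,,6.57e3,,-5.21,,298.15
FT@CB7,itc,1.12,4.95e4,-11.08,-6.40,-4.68,298.15
FT@CB7,uvvis,,1.30e4,,-5.62,,298.15
NT@CB7,itc,0.95,1.34e4,-15.60,-5.64,-9.96,298.15
NT@CB7,uvvis,,1.05e5,,-6.85,,298.15
CT@CB7,mmgbsa,,,-37.55,-17.45,-20.10,298.15
FT@CB7,mmgbsa,,,-33.12,-12.25,-20.86,298.15
NT@CB7,mmgbsa,,,-32.47,-12.79,-19.68,298.15
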