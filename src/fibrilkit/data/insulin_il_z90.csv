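condition,z90_nm,z90_err_nm
control,10.36,0.15
EMIM Cl [25 mM],12.37,0.16
EMIM AC [25 mM],16.56,0.59
EMIM BF4 [25 mM],21.58,0.77
EMIM NO3 [25 mM],24.84,0.42
EMIM HSO4 [25 mM],50.89,1.02
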