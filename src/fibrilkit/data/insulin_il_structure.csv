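condition,state,random_helix_pct,beta_sheet_pct,beta_turn_pct
control,monomer,53.7,19.6,24.4
EMIM HSO4 [25 mM],monomer,47.3,15.1,34.5
EMIM AC [25 mM],monomer,44.8,18.4,35.0
EMIM Cl [25 mM],monomer,46.0,19.0,30.7
EMIM NO3 [25 mM],monomer,46.2,13.7,35.8
EMIM BF4 [25 mM],monomer,40.7,15.9,38.2
control,fibril,14.4,58.6,21.2
EMIM HSO4 [25 mM],fibril,14.0,55.1,21.8
EMIM AC [25 mM],fibril,12.9,59.8,23.1
EMIM Cl [25 mM],fibril,13.1,59.6,23.3
EMIM NO3 [25 mM],fibril,20.0,51.7,24.1
EMIM BF4 [25 mM],fibril,13.1,57.0,26.3
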