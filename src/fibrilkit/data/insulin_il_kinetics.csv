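condition,t_lag_min,t_lag_err,t_half_min,t_half_err,k_agg_min_inv,k_agg_err
control,66.93,1.65,79.42,0.92,0.160,0.024
EMIM HSO4 [10 mM],33.61,0.69,35.71,0.38,0.952,0.301
EMIM HSO4 [25 mM],34.17,1.28,35.48,0.43,1.519,1.024
EMIM HSO4 [100 mM],29.14,0.15,31.09,0.06,1.028,0.069
EMIM AC [10 mM],39.39,2.13,50.53,1.20,0.179,0.030
EMIM AC [25 mM],32.00,1.14,37.66,0.53,0.353,0.060
EMIM AC [100 mM],24.18,0.21,25.28,0.09,1.822,0.419
EMIM Cl [10 mM],45.46,1.85,55.78,0.99,0.194,0.039
EMIM Cl [25 mM],32.49,0.73,38.79,0.36,0.318,0.041
EMIM Cl [100 mM],22.91,0.05,23.94,0.04,1.951,0.119
EMIM NO3 [10 mM],40.95,0.79,43.92,0.33,0.672,0.158
EMIM NO3 [25 mM],26.18,0.72,30.29,0.42,0.487,0.086
EMIM NO3 [100 mM],16.74,2.21,20.16,1.09,0.585,0.238
EMIM BF4 [10 mM],31.01,1.12,36.69,0.42,0.352,0.057
EMIM BF4 [25 mM],30.62,0.82,33.40,0.30,0.718,0.174
EMIM BF4 [100 mM],16.85,0.98,19.73,0.46,0.695,0.170
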