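name,sem_peak_density,n_peak_density,sem_v_half_act,n_v_half_act,sem_v_half_inact,n_v_half_inact,sem_persistent_pct,n_persistent_pct,sem_tau_rec,n_tau_rec
WT,55,22,0.42,22,0.96,22,0.29,22,0.03,18
N1662D,17,16,0.44,16,1.3,16,,,0.02,14
Q1494A,28,6,0.47,6,2.1,6,,,0.04,5
Q1494E,54,6,0.72,6,1.3,6,,,0.04,6
Q1494L,14,7,0.74,7,1.4,7,,,0.03,7
Q1494K,7.9,9,0.58,9,0.46,8,,,0.08,8
F1651C,60,7,0.59,7,0.53,7,0.57,7,0.02,6
M1501V,51,7,0.61,7,0.68,6,0.79,7,0.04,7
M1501T,27,6,0.58,6,0.54,6,0.96,6,0.01,6
L1657P,24,7,0.84,7,3.7,7,,,0.03,6
P1658S,22,9,0.57,9,0.68,9,0.99,9,0.02,7
A1659V,50,10,0.63,10,0.60,10,0.43,10,0.05,9
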