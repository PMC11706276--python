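name,peak_density_pA_per_pF,v_half_act_mV,k_act_mV,v_half_inact_mV,k_inact_mV,persistent_frac,tau_rec_ms,tau_inact_ms,e_na_mV,non_inactivating
WT,458.3,-17.56,6.0,-51.70,6.0,0.0106,1.19,3.0,65.0,false
N1662D,95.2,-17.24,6.0,-39.56,6.0,0.8,0.54,3.0,65.0,true
Q1494A,212.7,-13.39,6.0,-36.75,6.0,0.8,0.51,3.0,65.0,true
Q1494E,195.8,-16.01,6.0,-36.15,6.0,0.3,0.61,3.0,65.0,false
Q1494L,103.0,-15.28,6.0,-43.02,6.0,0.8,0.69,3.0,65.0,true
Q1494K,38.3,-9.03,6.0,-43.22,6.0,0.15,1.01,3.0,65.0,false
F1651C,461.5,-16.12,6.0,-38.92,6.0,0.0486,0.67,3.0,65.0,false
M1501V,265.4,-10.81,6.0,-42.63,6.0,0.0404,0.84,3.0,65.0,false
M1501T,275.2,-18.18,6.0,-46.37,6.0,0.0363,0.69,3.0,65.0,false
L1657P,109.8,-16.51,6.0,-44.82,6.0,0.8,0.62,3.0,65.0,true
P1658S,140.6,-14.34,6.0,-42.62,6.0,0.0591,0.59,3.0,65.0,false
A1659V,361.3,-17.00,6.0,-46.66,6.0,0.0564,0.77,3.0,65.0,false
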