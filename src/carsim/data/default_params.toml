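# Calibrated default model parameters.
# Written by scripts/calibrate.py -- see docs/methods.md for the provenance
# of each value (literature-anchored where available, otherwise calibrated
# against the observables of the 75-um-disk light protocols).
# Units: um^2/s (D_*), 1/s (first-order rates), 1/(uM s) (second-order
# rates), uM (concentrations), stress in units of Gamma (Gamma = 1).

[params]
D_C = 200.0
D_D = 135.0
D_E = 135.0
D_T = 10.0
k_ph = 100.0
f_deg = 0.1
k_onD = 0.01
k_offD = 0.0001
k_onT = 0.006
k_offT = 0.3
k_bind = 0.025
k_bind0 = 1.0e-5
k_u0 = 0.01
k_uCa = 0.001
sigma0 = 10.0
C_sat = 1200.0
mu0 = 0.15
p_stiff = 1.0
lambda_ratio = 1.0
mu_floor = 0.1
g_max = -0.075
Gamma = 1.0
C_T_tot = 540.0
C_D_tot = 6800.0
C_Ca_tot = 3400.0
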