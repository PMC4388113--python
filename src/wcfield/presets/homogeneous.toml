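# Space-independent reference column of the 1-D Wilson-Cowan model.
# Units: tau ms, b mV*ms, sigma um, Smax 1/ms, a 1/mV, theta mV, P/Q mV.
# P is the bifurcation control parameter (interesting range ~[0.9, 3.3] mV);
# the value below is a mid-range default that sweeps and scenarios override.
# The couplings are shared with the "space" column; b_IE = 19 mV*ms is the
# value that places the fold at P_SN = 1.7892426576 mV and the top-branch
# Hopf at P_HB = 2.1971513755 mV (reference values for this column).
tau_E = 10.0
tau_I = 8.0
b_EE = 18.0
b_EI = 10.0
b_IE = 19.0
b_II = 0.0
sigma_EE = 50.0
sigma_EI = 110.0
sigma_IE = 110.0
sigma_II = 20.0
Smax_E = 0.1
Smax_I = 0.15
a_E = 9.0
a_I = 9.0
theta_E = 2.2
theta_I = 2.2
P = 2.0
Q = 1.35
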