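# Space-dependent ("cortical rod") column of the 1-D Wilson-Cowan model.
# Two sigma_EE variants (43 and 50 um) are in use for this column; 50 um is
# the default here because it reproduces the reference dispersion peaks
# (Turing mode near 1.6 waves/mm at P = 2.34 mV, sigma_EI,IE = 200 um, and
# 2.62 waves/mm at P = 2 mV, sigma_EI,IE = 112 um); override to 43 for the
# sharper-kernel variant.  sigma_EI and sigma_IE are the Turing control
# parameters (useful range ~[42, 148.5] um, up to 200 um for strongly
# supercritical pattern formation).
tau_E = 10.0
tau_I = 8.0
b_EE = 18.0
b_EI = 10.0
b_IE = 19.0
b_II = 0.0
sigma_EE = 50.0
sigma_EI = 112.0
sigma_IE = 112.0
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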