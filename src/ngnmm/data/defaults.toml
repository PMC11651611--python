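# Reference parameter set for the E-I next-generation neural mass network.
# Time in seconds, potentials in mV. These values place the network steady
# state close to a Hopf bifurcation.

[node]
tau_E = 0.011
tau_I = 0.012
eta0_E = -2.5
eta0_I = 3.0
delta_E = 0.5
delta_I = 0.5
alpha_EE = 50.0
alpha_EI = 40.0
alpha_IE = 50.0
alpha_II = 40.0
kappa_s_EE = 0.5
kappa_s_EI = 0.3
kappa_s_IE = 0.7
kappa_s_II = 0.3
v_syn_EE = 10.0
v_syn_EI = -10.0
v_syn_IE = 10.0
v_syn_II = -10.0
kappa_v_EE = 0.01
kappa_v_EI = 0.0
kappa_v_IE = 0.0
kappa_v_II = 0.025

[network]
k_ext = 0.2
alpha_net = 40.0
v_syn_net = 10.0
speed = 12.0
shunting_network_input = true

[bold]
rho = 0.34
tau_bold = 2.0
k = 0.65
gamma = 0.41
alpha_grubb = 0.32
V0 = 0.02
k1 = 3.72
k2 = 0.527
k3 = 0.53
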