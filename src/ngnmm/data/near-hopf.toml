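# Operating point near the network Hopf bifurcation: sustained but
# near-linear oscillations, FC well approximated by the leading eigenmodes.
[network]
k_ext = 0.2

[run]
duration = 60.0
transient = 4.0
fs_out = 600.0
seed = 0
bands = ["delta", "theta", "alpha", "beta1", "beta2", "gamma1", "gamma2", "gamma3"]
metric = "GIM"
bold = true
sf_clustering = true

[run.connectome.synthetic]
n_regions = 68
seed = 0
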