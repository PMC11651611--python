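# Strongly coupled nonlinear regime: no uniform steady state (the run
# starts from the zero-coupling equilibrium), large complex oscillations,
# band-specific FC patterns.
[network]
k_ext = 0.5

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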