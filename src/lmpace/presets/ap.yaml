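# Aliev-Panfilov two-variable model in a spiral-breakup regime
# (raised threshold a with faster, weakly voltage-coupled recovery),
# which sustains electrical turbulence on the published grid.
# Native time is dimensionless; time_scale converts to ms.
K: 8.0
a: 0.1
b: 0.1
eps0: 0.01
mu1: 0.12
mu2: 0.3
time_scale: 1.0    # ms per native time unit
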