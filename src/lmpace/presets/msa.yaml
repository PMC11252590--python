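# Mitchell-Schaeffer two-current model, ischaemic adaptation:
# slowed depolarization (tau_in) and prolonged recovery/closing times
# relative to the textbook set, calibrated against the tabulated
# chaos characteristics (dominant frequency, upward-deflection
# statistics) of the published grid. Time constants in ms.
tau_in: 0.72
tau_out: 7.0
tau_open: 100.0
tau_close: 210.0
v_gate: 0.13
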