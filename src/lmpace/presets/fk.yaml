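# Fenton-Karma three-current model. Kinetics of the original
# three-current formulation's modified-Luo-Rudy-I parameterization,
# which sustains spiral-wave breakup on the published grid; calibrated
# against the tabulated chaos characteristics (dominant frequency,
# upward-deflection statistics). Time constants in ms, potentials
# dimensionless in [0, ~1].
tau_d: 0.1724    # fast inward (depolarization); C_m / g_fi
tau_r: 130.0     # repolarization (slow outward, excited branch)
tau_si: 127.0    # slow inward
tau_0: 12.5      # slow outward, resting branch
tau_vp: 10.0     # v-gate closing (excited)
tau_v1m: 18.2    # v-gate reopening, u >= u_v
tau_v2m: 18.2    # v-gate reopening, u < u_v
tau_wp: 1020.0   # w-gate closing (excited)
tau_wm: 80.0     # w-gate reopening
u_c: 0.13        # excitation threshold
u_v: 0.025       # v-gate branch threshold
u_csi: 0.85      # slow-inward activation midpoint
kappa: 10.0      # slow-inward activation steepness
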