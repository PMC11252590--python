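# Bueno-Orovio-Cherry-Fenton minimal ventricular model,
# epicardial parameter set. Time constants in ms.
u_o: 0.0
u_u: 1.55
theta_v: 0.3
theta_w: 0.13
theta_vm: 0.006
theta_o: 0.006
tau_v1m: 60.0
tau_v2m: 1150.0
tau_vp: 1.4506
tau_w1m: 60.0
tau_w2m: 15.0
k_wm: 65.0
u_wm: 0.03
tau_wp: 200.0
tau_fi: 0.11
tau_o1: 400.0
tau_o2: 6.0
tau_so1: 30.0181
tau_so2: 0.9957
k_so: 2.0458
u_so: 0.65
tau_s1: 2.7342
tau_s2: 16.0
k_s: 2.0994
u_s: 0.9087
tau_si: 1.8875
tau_winf: 0.07
w_inf_star: 0.94
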