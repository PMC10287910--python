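# Walker-A K124R: binds ATP (reduced extent), no hydrolysis, no stimulation.
[rates]
k1 = 1.8e-3
k_minus1 = 0.018
k2 = 0.017
k2_dna_factor = 3.0
k3 = 0.05
k_minus3 = 0.02
coop_omega = 4.0
k4 = 0.0
stim_dna = 1.0
stim_parb = 1.0
stim_both = 1.0
kcat = 0.0
k5 = 9.4e-3
k_minus5 = 0.075
k6_adp_to_atp = 6.5e-4
k6_adp_to_adp = 6.1e-4
k6_atp_to_atp = 1.4e-3
k_star_relax = 0.01
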