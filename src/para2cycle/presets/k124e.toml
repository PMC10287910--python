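# Walker-A K124E: no ATP binding, no hydrolysis; ParA2 stays in the apo/ADP pool.
[rates]
k1 = 0.0
k_minus1 = 0.0
k2 = 0.0
k2_dna_factor = 1.0
k3 = 0.05
k_minus3 = 0.02
coop_omega = 4.0
k4 = 0.0
stim_dna = 1.0
stim_parb = 1.0
stim_both = 1.0
kcat = 0.0
k5 = 0.0
k_minus5 = 0.0
k6_adp_to_atp = 0.0
k6_adp_to_adp = 0.0
k6_atp_to_atp = 0.0
k_star_relax = 0.01
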