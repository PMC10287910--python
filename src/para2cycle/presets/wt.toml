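# Alias of the wild-type defaults.
[rates]
k1 = 3.6e-3
k_minus1 = 0.018
k2 = 0.017
k2_dna_factor = 3.0
k3 = 0.05
k_minus3 = 0.02
coop_omega = 4.0
k4 = 0.08
stim_dna = 2.0
stim_parb = 3.0
stim_both = 8.0
kcat = 5e-4
k5 = 9.4e-3
k_minus5 = 0.075
k6_adp_to_atp = 6.5e-4
k6_adp_to_adp = 6.1e-4
k6_atp_to_atp = 1.4e-3
k_star_relax = 0.01
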