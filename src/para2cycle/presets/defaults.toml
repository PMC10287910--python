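# Wild-type ParA2 ATPase-cycle rate constants (the versioned defaults file).
# First-order rates per-s; second-order per-uM per-s; factors dimensionless.
# Calibrated against the printed in-vitro kinetics: MANT-ATP binding kobs
# 0.09-0.13 /s at 25 uM, chase slow phase 0.015-0.02 /s, MANT-ADP chase
# 0.07-0.08 /s with KD 8 uM, tryptophan switch kobs 0.015-0.018 /s (x2-5
# with DNA), DNA-carpet binding 0.05 /s and wash 0.1 /s at 1 uM, ATPgS
# carpet rates ~0.02 /s, exchange kon 6.5e-4 / 6.1e-4 / 1.4e-3 per-uM per-s,
# hydrolysis stimulation 2x (DNA), 3x (ParB2), 8x (both).

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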