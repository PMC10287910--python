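# Two-state thermal-melt parameters from CD at 220 nm (theta_220), scanned
# 23-63 C.  Baselines in a.u.; slope is the transition width (C).

[apo]
tm_C = 44.0
slope_C = 1.5
theta_folded = -10.0
theta_unfolded = -2.0

[atp]
tm_C = 53.0
slope_C = 1.5
theta_folded = -10.0
theta_unfolded = -2.0

[adp]
tm_C = 51.0
slope_C = 1.5
theta_folded = -10.0
theta_unfolded = -2.0

[atpgs]
tm_C = 50.0
slope_C = 1.5
theta_folded = -10.0
theta_unfolded = -2.0

[amppnp]
tm_C = 44.0
slope_C = 1.5
theta_folded = -10.0
theta_unfolded = -2.0

[atp-no-mg]
tm_C = 44.0
slope_C = 1.5
theta_folded = -10.0
theta_unfolded = -2.0
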