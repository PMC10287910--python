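# Double-exponential FRAP parameters of ParA2-GFP on the DNA carpet.
# low-density: 28% carpet density; parb-1to2: ParA2:ParB2 mixed 1:2.
# Fractions for the ParB2 and high-density conditions are not printed
# (the fast fraction shifts toward immobile); values are declared
# assumptions in the methods note.

[low-density]
fraction_fast = 0.64
fraction_slow = 0.23
fraction_immobile = 0.13
tau_fast_s = 2.3
tau_slow_s = 121.0

[high-density]
fraction_fast = 0.45
fraction_slow = 0.30
fraction_immobile = 0.25
tau_fast_s = 8.3
tau_slow_s = 150.0

[parb-1to2]
fraction_fast = 0.40
fraction_slow = 0.25
fraction_immobile = 0.35
tau_fast_s = 8.2
tau_slow_s = 308.0
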