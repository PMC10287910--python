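# Cooperative Hill parameters for ParA2 binding a 69 bp nonspecific duplex
# (gel-shift titrations, 5 nM labelled DNA).  kd in nM.  Hill coefficients
# for conditions other than WT+ATP (n = 4) are not printed and are fixed
# assumptions declared in the methods note.

[wt-atp]
kd_nM = 46.0
n = 4.0
plateau = 1.0

[wt-atpgs]
kd_nM = 34.0
n = 4.0
plateau = 1.0

[wt-adp]
kd_nM = 378.0
n = 2.0
plateau = 1.0

[apo]
kd_nM = 1000.0
n = 1.5
plateau = 1.0

[k124r]
kd_nM = 47.1
n = 4.0
plateau = 1.0

[k124q]
kd_nM = 137.5
n = 3.0
plateau = 1.0

[k124e]
kd_nM = 452.0
n = 2.0
plateau = 1.0
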