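patient,p_systolic_mmhg,p_diastolic_mmhg
1,161.5,73
2,158.3,77
3,112.9,73
4,148.5,80
5,151.9,105
6,159.5,75
7,105.4,75
8,116.9,74
9,135,62
10,124.4,93
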