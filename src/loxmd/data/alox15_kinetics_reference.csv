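enzyme,substrate,kcat_per_s,kcat_se,KM_uM,KM_se
WT,LA,47.2,2.8,21.4,1.3
WT,AA,11.3,0.6,8.1,0.4
His585Glu,LA,21.2,3.1,19.8,2.9
His585Glu,AA,15.8,0.9,4.9,0.3
Trp181Glu,LA,39.8,6.2,24.7,3.9
Trp181Glu,AA,54.40,2.01,6.6,0.4
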