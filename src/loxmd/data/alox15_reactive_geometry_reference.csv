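system,substrate,mean_d_C_OH,mean_d_HproS_OH,mean_d_HproR_OH,pct_well_oriented,pct_precatalytic
Trp181Glu,AA,3.70,4.50,3.15,99.10,55.69
WT,AA,5.19,4.85,5.47,97.78,3.40
Trp181Glu,LA,4.26,4.17,4.18,87.99,22.65
WT,LA,4.58,4.74,4.56,90.09,14.40
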