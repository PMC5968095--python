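conc_mM,mean_nondifferentiated,sd_nondifferentiated,n_embryoid_bodies,n_tests
0.00,1.5,0.89,24,6
0.28,2.67,2.12,24,6
0.55,2.67,2.05,24,6
1.11,6.33,3.92,24,6
2.77,16.83,3.76,24,6
5.55,23.33,1.02,24,6
11.10,24.00,0.53,24,6
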