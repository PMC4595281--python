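control,mm_emg_ua,mm_emg_aa,mm_emg_uf,mm_emg_af,mm_glove_ua,mm_glove_aa,compliance_ua,compliance_aa,n_movements_ua,n_movements_aa
1,0.18,0.16,0.36,0.20,0.02,0,0.71,0.71,89,89
2,4.47,2.09,0.39,0.33,0.01,-0.06,0.91,0.87,97,92
3,3.33,1.57,1.63,0.00,0.06,-0.27,0.19,0.27,81,96
4,0.39,0.86,0.02,0.01,0,-0.01,0.81,0.51,93,100
5,0.05,0.23,0.29,0.01,-0.15,,0.9,,90,
6,0.01,0.02,2.57,0.15,-0.11,-0.2,0.35,0.7,93,97
7,0.01,0.09,0.11,4.54,0.03,0.06,0.92,0.88,92,93
8,0.08,6.01,0.03,0.00,0.18,0.1,0.83,0.76,90,94
9,3.42,0.03,0.66,3.75,0.07,,0.86,,93,
10,0.23,0.54,2.87,4.64,0.11,-0.17,0.63,0.49,95,93
11,1.30,10.39,1.23,9.84,0.19,-0.2,0.56,0.81,82,88
12,7.89,0.46,1.17,1.06,-0.1,-0.32,0.72,0.62,94,93
13,0.08,0.99,5.96,0.00,0.36,0.01,0.74,0.43,105,80
14,0.03,0.00,0.04,0.26,-0.01,-0.07,0.88,0.82,91,85
15,0.34,29.91,0.02,7.36,-0.06,-0.06,0.87,0.66,88,91
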