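patient,mm_emg_ua,mm_emg_aa,mm_emg_uf,mm_emg_af,mm_glove_ua,mm_glove_aa,compliance_ua,compliance_aa,n_movements_ua,n_movements_aa
1,0.43,0.08,0.07,0.59,-0.17,-0.16,0.77,0.78,92,89
2,0.64,0.77,0.22,0.01,-0.08,0.16,0.82,0.79,92,92
3,0.02,0.06,0.00,0.26,-0.12,-0.16,0.89,0.88,92,89
4,0.00,0.78,0.04,0.08,-0.03,-0.04,0.68,0.77,98,98
5,,0.60,0.02,0.02,-0.17,,0.96,,87,
6,0.07,1.13,0.01,0.01,0.33,-0.15,0.39,0.47,81,84
7,4.65,10.80,4.95,43.18,,,,,,
8,,,20.13,,0.06,-0.03,0.27,0.83,86,86
9,0.16,0.02,0.01,4.10,0.19,-0.01,0.71,0.6,75,64
10,0.07,0.00,0.19,0.44,0.15,-0.06,0.8,0.8,91,95
11,2.40,24.50,0.05,1.06,-0.09,-0.13,0.85,0.52,90,84
12,0.05,0.27,0.07,0.35,-0.12,-0.15,0.87,0.66,88,89
13,0.01,9.02,0.01,45.13,-0.18,0.38,0.86,0.85,97,92
14,0.01,1.38,0.02,0.15,0.01,,0.15,,85,
15,4.55,0.08,0.05,0.97,-0.07,0.01,0.61,0.78,86,93
16,1.48,0.77,0.00,0.61,0.08,-0.09,0.67,0.48,102,86
17,0.31,0.11,0.13,0.75,-0.03,-0.07,0.72,0.66,98,98
18,0.33,0.25,1.35,0.22,-0.04,0.05,0.77,0.68,95,93
19,0.08,0.21,0.05,0.30,-0.04,0.21,0.86,0.85,94,82
20,0.03,0.08,25.27,0.03,-0.03,0.16,0.72,0.55,90,94
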