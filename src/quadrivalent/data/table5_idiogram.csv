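karyotype,chrom_index,homolog_id,rl_mean,rl_sd,ar_mean,ar_sd,focal_code
I,1,1,16.61,0.52,1.23,0.12,M
I,1,2,16.61,0.52,1.23,0.12,M
I,2,1,13.92,0.75,2.51,0.41,
I,2,2,13.92,0.75,2.51,0.41,
I,3,1,11.50,0.87,2.31,0.19,
I,3,2,11.50,0.87,2.31,0.19,
I,4,1,10.77,0.45,1.52,0.18,
I,4,2,10.77,0.45,1.52,0.18,
I,5,1,9.85,0.94,1.35,0.12,
I,5,2,9.85,0.94,1.35,0.12,
I,6,1,6.09,0.34,1.27,0.11,m
I,6,2,6.09,0.34,1.27,0.11,m
I,7,1,5.38,0.24,2.37,0.41,
I,7,2,5.38,0.24,2.37,0.41,
I,8,1,5.25,0.17,1.38,0.18,
I,8,2,5.25,0.17,1.38,0.18,
I,9,1,4.89,0.41,2.11,0.30,
I,9,2,4.89,0.41,2.11,0.30,
I,10,1,4.64,0.31,1.28,0.20,
I,10,2,4.64,0.31,1.28,0.20,
I,11,1,4.12,0.28,1.18,0.20,
I,11,2,4.12,0.28,1.18,0.20,
I,12,1,3.68,0.28,1.19,0.14,
I,12,2,3.68,0.28,1.19,0.14,
I,13,1,3.30,0.33,1.19,0.14,
I,13,2,3.30,0.33,1.19,0.14,
IV,1,1,13.03,0.55,1.19,0.09,M
IV,1,2,8.32,0.60,7.11,0.11,T
IV,2,1,11.34,0.42,2.49,0.21,
IV,2,2,11.34,0.42,2.49,0.21,
IV,3,1,9.63,0.70,2.54,0.54,
IV,3,2,9.63,0.70,2.54,0.54,
IV,4,1,8.96,0.39,1.47,0.13,
IV,4,2,8.96,0.39,1.47,0.13,
IV,5,1,8.19,0.57,1.32,0.12,
IV,5,2,8.19,0.57,1.32,0.12,
IV,6,1,5.01,0.34,1.17,0.11,m
IV,6,2,9.02,0.66,3.35,0.31,St
IV,7,1,4.69,0.20,2.04,0.30,
IV,7,2,4.69,0.20,2.04,0.30,
IV,8,1,4.38,0.28,1.25,0.14,
IV,8,2,4.38,0.28,1.25,0.14,
IV,9,1,4.08,0.21,2.00,0.24,
IV,9,2,4.08,0.21,2.00,0.24,
IV,10,1,3.92,0.23,1.22,0.08,
IV,10,2,3.92,0.23,1.22,0.08,
IV,11,1,3.47,0.34,1.23,0.16,
IV,11,2,3.47,0.34,1.23,0.16,
IV,12,1,3.19,0.27,1.16,0.16,
IV,12,2,3.19,0.27,1.16,0.16,
IV,13,1,2.76,0.26,1.18,0.16,
IV,13,2,2.76,0.26,1.18,0.16,
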