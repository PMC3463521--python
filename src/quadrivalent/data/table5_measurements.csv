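cell_id,chrom_index,homolog_id,relative_length,arm_ratio,has_5S_signal
typeI,1,1,16.61,1.23,True
typeI,1,2,16.61,1.23,True
typeI,2,1,13.92,2.51,False
typeI,2,2,13.92,2.51,False
typeI,3,1,11.50,2.31,False
typeI,3,2,11.50,2.31,False
typeI,4,1,10.77,1.52,False
typeI,4,2,10.77,1.52,False
typeI,5,1,9.85,1.35,False
typeI,5,2,9.85,1.35,False
typeI,6,1,6.09,1.27,False
typeI,6,2,6.09,1.27,False
typeI,7,1,5.38,2.37,False
typeI,7,2,5.38,2.37,False
typeI,8,1,5.25,1.38,False
typeI,8,2,5.25,1.38,False
typeI,9,1,4.89,2.11,False
typeI,9,2,4.89,2.11,False
typeI,10,1,4.64,1.28,False
typeI,10,2,4.64,1.28,False
typeI,11,1,4.12,1.18,False
typeI,11,2,4.12,1.18,False
typeI,12,1,3.68,1.19,False
typeI,12,2,3.68,1.19,False
typeI,13,1,3.30,1.19,False
typeI,13,2,3.30,1.19,False
typeIV,1,1,13.03,1.19,True
typeIV,1,2,8.32,7.11,True
typeIV,2,1,11.34,2.49,False
typeIV,2,2,11.34,2.49,False
typeIV,3,1,9.63,2.54,False
typeIV,3,2,9.63,2.54,False
typeIV,4,1,8.96,1.47,False
typeIV,4,2,8.96,1.47,False
typeIV,5,1,8.19,1.32,False
typeIV,5,2,8.19,1.32,False
typeIV,6,1,5.01,1.17,False
typeIV,6,2,9.02,3.35,False
typeIV,7,1,4.69,2.04,False
typeIV,7,2,4.69,2.04,False
typeIV,8,1,4.38,1.25,False
typeIV,8,2,4.38,1.25,False
typeIV,9,1,4.08,2.00,False
typeIV,9,2,4.08,2.00,False
typeIV,10,1,3.92,1.22,False
typeIV,10,2,3.92,1.22,False
typeIV,11,1,3.47,1.23,False
typeIV,11,2,3.47,1.23,False
typeIV,12,1,3.19,1.16,False
typeIV,12,2,3.19,1.16,False
typeIV,13,1,2.76,1.18,False
typeIV,13,2,2.76,1.18,False
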