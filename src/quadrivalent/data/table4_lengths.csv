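cell_id,chrom,length_um
1,1-1,5.38
1,1-2,3.13
1,6-1,2.24
1,6-2,3.36
2,1-1,9.07
2,1-2,5.82
2,6-1,3.00
2,6-2,6.48
3,1-1,7.60
3,1-2,4.45
3,6-1,3.03
3,6-2,5.08
4,1-1,9.58
4,1-2,6.46
4,6-1,3.38
4,6-2,6.59
5,1-1,7.19
5,1-2,4.25
5,6-1,2.81
5,6-2,4.98
6,1-1,6.02
6,1-2,3.60
6,6-1,2.39
6,6-2,4.30
7,1-1,5.02
7,1-2,3.40
7,6-1,2.06
7,6-2,3.63
8,1-1,5.71
8,1-2,3.91
8,6-1,2.05
8,6-2,3.49
9,1-1,4.70
9,1-2,3.17
9,6-1,2.00
9,6-2,3.25
10,1-1,4.99
10,1-2,3.46
10,6-1,2.15
10,6-2,4.02
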