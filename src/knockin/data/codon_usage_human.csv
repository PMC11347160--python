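# Human codon usage, standard genome-wide per-codon fractions
# (Kazusa-style table, per-thousand values divided by 1000; sums to ~1).
codon,freq
TTT,0.0176
TTC,0.0203
TTA,0.0077
TTG,0.0129
CTT,0.0132
CTC,0.0196
CTA,0.0072
CTG,0.0396
ATT,0.0160
ATC,0.0208
ATA,0.0075
ATG,0.0220
GTT,0.0110
GTC,0.0145
GTA,0.0071
GTG,0.0281
TCT,0.0152
TCC,0.0177
TCA,0.0122
TCG,0.0044
CCT,0.0175
CCC,0.0198
CCA,0.0169
CCG,0.0069
ACT,0.0131
ACC,0.0189
ACA,0.0151
ACG,0.0061
GCT,0.0184
GCC,0.0277
GCA,0.0158
GCG,0.0074
TAT,0.0122
TAC,0.0153
TAA,0.0010
TAG,0.0008
CAT,0.0109
CAC,0.0151
CAA,0.0123
CAG,0.0342
AAT,0.0170
AAC,0.0191
AAA,0.0244
AAG,0.0319
GAT,0.0218
GAC,0.0251
GAA,0.0290
GAG,0.0396
TGT,0.0106
TGC,0.0126
TGA,0.0016
TGG,0.0132
CGT,0.0045
CGC,0.0104
CGA,0.0062
CGG,0.0114
AGT,0.0121
AGC,0.0195
AGA,0.0122
AGG,0.0120
GGT,0.0108
GGC,0.0222
GGA,0.0165
GGG,0.0165
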