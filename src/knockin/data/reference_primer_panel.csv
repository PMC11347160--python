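# Reference primer panel: 18-25-mers with melting temperatures computed
# once by an independent nearest-neighbor oracle (unified NN parameters,
# 50 mM monovalent + 1.5 mM Mg2+ / 0.6 mM dNTP equivalent, 50 nM primer).
sequence,tm
AGGCGTCGATGCCGATCCCACGGA,73.613
GATAACCGATACTCGACATCCGTCA,63.616
GACCGGCTGAAATATCAGCA,60.004
AATGTCGACATCGCCCCGCAACATC,69.564
GTATTCCCAGGCTCCCTTG,59.277
ATCCCCGGCAGTAGAACGA,62.49
TGTGTGGTTAGTACGCAAAACT,60.26
CGGCGGTAGGATCCACGCGTCACAA,72.362
TGACATCCGGCGAAACTACGCTT,66.579
AGATGAGTTAGGTGCTAATAACAAG,58.267
ATTTATCCGCTCTCCCCTACA,59.959
AAGCCGCTGTTCTAAGCTT,59.436
TTAGCTGTACCTGCAGATG,56.329
GATGCGCACGAACCGCCGGAC,70.964
TTTGGATTCTAAAGGTTTATATCA,53.535
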