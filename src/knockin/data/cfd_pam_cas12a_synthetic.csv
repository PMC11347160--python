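# SYNTHETIC PAM-factor table for enAsCas12a (5' TTTV PAM). Constructed
# stand-in encoding the enzyme's PAM preference: canonical TTTV = 1.0,
# TTTT strongly reduced, single-base deviations from TTTN weakly tolerated
# (enAsCas12a's relaxed PAM recognition), everything else 0.
# Key is the full 4-nt PAM.
pam,factor
TTTA,1.0
TTTC,1.0
TTTG,1.0
TTTT,0.1
ATTA,0.05
ATTC,0.05
ATTG,0.05
CTTA,0.05
CTTC,0.05
CTTG,0.05
GTTA,0.05
GTTC,0.05
GTTG,0.05
TATA,0.02
TATC,0.02
TATG,0.02
TCTA,0.02
TCTC,0.02
TCTG,0.02
TGTA,0.02
TGTC,0.02
TGTG,0.02
TTAA,0.02
TTAC,0.02
TTAG,0.02
TTCA,0.02
TTCC,0.02
TTCG,0.02
TTGA,0.02
TTGC,0.02
TTGG,0.02
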