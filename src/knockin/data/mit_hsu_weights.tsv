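# Single-mismatch position weights for the MIT (Hsu et al. 2013) off-target
# hit score, as used by CRISPOR's calcHitScore. Position 1 = PAM-distal end
# of the 20-nt protospacer; position 20 = PAM-proximal.
# position	weight
1	0.000
2	0.000
3	0.014
4	0.000
5	0.000
6	0.395
7	0.317
8	0.000
9	0.389
10	0.079
11	0.445
12	0.508
13	0.613
14	0.851
15	0.732
16	0.828
17	0.615
18	0.804
19	0.685
20	0.583
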