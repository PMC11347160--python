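# SYNTHETIC CFD mismatch-factor table for SpCas9, 20-nt spacer.
# Constructed stand-in for the published CFD mismatch table: factors are a
# deterministic positional model with PAM-proximal mismatches most
# deleterious and transition mismatches more tolerated than transversions.
# position 1 = PAM-distal. Key: (position, guide base, off-target site base),
# both on the protospacer strand.
position,guide,site,factor
1,A,C,0.779
1,A,G,1.0
1,A,T,0.779
1,C,A,0.779
1,C,G,0.779
1,C,T,1.0
1,G,A,1.0
1,G,C,0.779
1,G,T,0.779
1,T,A,0.779
1,T,C,1.0
1,T,G,0.779
2,A,C,0.7397
2,A,G,1.0
2,A,T,0.7397
2,C,A,0.7397
2,C,G,0.7397
2,C,T,1.0
2,G,A,1.0
2,G,C,0.7397
2,G,T,0.7397
2,T,A,0.7397
2,T,C,1.0
2,T,G,0.7397
3,A,C,0.7005
3,A,G,1.0
3,A,T,0.7005
3,C,A,0.7005
3,C,G,0.7005
3,C,T,1.0
3,G,A,1.0
3,G,C,0.7005
3,G,T,0.7005
3,T,A,0.7005
3,T,C,1.0
3,T,G,0.7005
4,A,C,0.6612
4,A,G,0.9515
4,A,T,0.6612
4,C,A,0.6612
4,C,G,0.6612
4,C,T,0.9515
4,G,A,0.9515
4,G,C,0.6612
4,G,T,0.6612
4,T,A,0.6612
4,T,C,0.9515
4,T,G,0.6612
5,A,C,0.6219
5,A,G,0.8949
5,A,T,0.6219
5,C,A,0.6219
5,C,G,0.6219
5,C,T,0.8949
5,G,A,0.8949
5,G,C,0.6219
5,G,T,0.6219
5,T,A,0.6219
5,T,C,0.8949
5,T,G,0.6219
6,A,C,0.5826
6,A,G,0.8384
6,A,T,0.5826
6,C,A,0.5826
6,C,G,0.5826
6,C,T,0.8384
6,G,A,0.8384
6,G,C,0.5826
6,G,T,0.5826
6,T,A,0.5826
6,T,C,0.8384
6,T,G,0.5826
7,A,C,0.5434
7,A,G,0.7819
7,A,T,0.5434
7,C,A,0.5434
7,C,G,0.5434
7,C,T,0.7819
7,G,A,0.7819
7,G,C,0.5434
7,G,T,0.5434
7,T,A,0.5434
7,T,C,0.7819
7,T,G,0.5434
8,A,C,0.5041
8,A,G,0.7254
8,A,T,0.5041
8,C,A,0.5041
8,C,G,0.5041
8,C,T,0.7254
8,G,A,0.7254
8,G,C,0.5041
8,G,T,0.5041
8,T,A,0.5041
8,T,C,0.7254
8,T,G,0.5041
9,A,C,0.4648
9,A,G,0.6689
9,A,T,0.4648
9,C,A,0.4648
9,C,G,0.4648
9,C,T,0.6689
9,G,A,0.6689
9,G,C,0.4648
9,G,T,0.4648
9,T,A,0.4648
9,T,C,0.6689
9,T,G,0.4648
10,A,C,0.4255
10,A,G,0.6124
10,A,T,0.4255
10,C,A,0.4255
10,C,G,0.4255
10,C,T,0.6124
10,G,A,0.6124
10,G,C,0.4255
10,G,T,0.4255
10,T,A,0.4255
10,T,C,0.6124
10,T,G,0.4255
11,A,C,0.3863
11,A,G,0.5558
11,A,T,0.3863
11,C,A,0.3863
11,C,G,0.3863
11,C,T,0.5558
11,G,A,0.5558
11,G,C,0.3863
11,G,T,0.3863
11,T,A,0.3863
11,T,C,0.5558
11,T,G,0.3863
12,A,C,0.347
12,A,G,0.4993
12,A,T,0.347
12,C,A,0.347
12,C,G,0.347
12,C,T,0.4993
12,G,A,0.4993
12,G,C,0.347
12,G,T,0.347
12,T,A,0.347
12,T,C,0.4993
12,T,G,0.347
13,A,C,0.3077
13,A,G,0.4428
13,A,T,0.3077
13,C,A,0.3077
13,C,G,0.3077
13,C,T,0.4428
13,G,A,0.4428
13,G,C,0.3077
13,G,T,0.3077
13,T,A,0.3077
13,T,C,0.4428
13,T,G,0.3077
14,A,C,0.2684
14,A,G,0.3863
14,A,T,0.2684
14,C,A,0.2684
14,C,G,0.2684
14,C,T,0.3863
14,G,A,0.3863
14,G,C,0.2684
14,G,T,0.2684
14,T,A,0.2684
14,T,C,0.3863
14,T,G,0.2684
15,A,C,0.2292
15,A,G,0.3298
15,A,T,0.2292
15,C,A,0.2292
15,C,G,0.2292
15,C,T,0.3298
15,G,A,0.3298
15,G,C,0.2292
15,G,T,0.2292
15,T,A,0.2292
15,T,C,0.3298
15,T,G,0.2292
16,A,C,0.1899
16,A,G,0.2733
16,A,T,0.1899
16,C,A,0.1899
16,C,G,0.1899
16,C,T,0.2733
16,G,A,0.2733
16,G,C,0.1899
16,G,T,0.1899
16,T,A,0.1899
16,T,C,0.2733
16,T,G,0.1899
17,A,C,0.1506
17,A,G,0.2167
17,A,T,0.1506
17,C,A,0.1506
17,C,G,0.1506
17,C,T,0.2167
17,G,A,0.2167
17,G,C,0.1506
17,G,T,0.1506
17,T,A,0.1506
17,T,C,0.2167
17,T,G,0.1506
18,A,C,0.1113
18,A,G,0.1602
18,A,T,0.1113
18,C,A,0.1113
18,C,G,0.1113
18,C,T,0.1602
18,G,A,0.1602
18,G,C,0.1113
18,G,T,0.1113
18,T,A,0.1113
18,T,C,0.1602
18,T,G,0.1113
19,A,C,0.0721
19,A,G,0.1037
19,A,T,0.0721
19,C,A,0.0721
19,C,G,0.0721
19,C,T,0.1037
19,G,A,0.1037
19,G,C,0.0721
19,G,T,0.0721
19,T,A,0.0721
19,T,C,0.1037
19,T,G,0.0721
20,A,C,0.0328
20,A,G,0.0472
20,A,T,0.0328
20,C,A,0.0328
20,C,G,0.0328
20,C,T,0.0472
20,G,A,0.0472
20,G,C,0.0328
20,G,T,0.0328
20,T,A,0.0328
20,T,C,0.0472
20,T,G,0.0328
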