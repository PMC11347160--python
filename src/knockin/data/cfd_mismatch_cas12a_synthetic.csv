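# SYNTHETIC CFD mismatch-factor table for enAsCas12a, 20-nt spacer.
# Constructed stand-in (see SpCas9 table note); for Cas12a the seed region
# is PAM-proximal, i.e. low positions here since position 1 is PAM-proximal
# for a 5'-PAM enzyme. Key: (position, guide base, site base).
position,guide,site,factor
1,A,C,0.0328
1,A,G,0.0472
1,A,T,0.0328
1,C,A,0.0328
1,C,G,0.0328
1,C,T,0.0472
1,G,A,0.0472
1,G,C,0.0328
1,G,T,0.0328
1,T,A,0.0328
1,T,C,0.0472
1,T,G,0.0328
2,A,C,0.0721
2,A,G,0.1037
2,A,T,0.0721
2,C,A,0.0721
2,C,G,0.0721
2,C,T,0.1037
2,G,A,0.1037
2,G,C,0.0721
2,G,T,0.0721
2,T,A,0.0721
2,T,C,0.1037
2,T,G,0.0721
3,A,C,0.1113
3,A,G,0.1602
3,A,T,0.1113
3,C,A,0.1113
3,C,G,0.1113
3,C,T,0.1602
3,G,A,0.1602
3,G,C,0.1113
3,G,T,0.1113
3,T,A,0.1113
3,T,C,0.1602
3,T,G,0.1113
4,A,C,0.1506
4,A,G,0.2167
4,A,T,0.1506
4,C,A,0.1506
4,C,G,0.1506
4,C,T,0.2167
4,G,A,0.2167
4,G,C,0.1506
4,G,T,0.1506
4,T,A,0.1506
4,T,C,0.2167
4,T,G,0.1506
5,A,C,0.1899
5,A,G,0.2733
5,A,T,0.1899
5,C,A,0.1899
5,C,G,0.1899
5,C,T,0.2733
5,G,A,0.2733
5,G,C,0.1899
5,G,T,0.1899
5,T,A,0.1899
5,T,C,0.2733
5,T,G,0.1899
6,A,C,0.2292
6,A,G,0.3298
6,A,T,0.2292
6,C,A,0.2292
6,C,G,0.2292
6,C,T,0.3298
6,G,A,0.3298
6,G,C,0.2292
6,G,T,0.2292
6,T,A,0.2292
6,T,C,0.3298
6,T,G,0.2292
7,A,C,0.2684
7,A,G,0.3863
7,A,T,0.2684
7,C,A,0.2684
7,C,G,0.2684
7,C,T,0.3863
7,G,A,0.3863
7,G,C,0.2684
7,G,T,0.2684
7,T,A,0.2684
7,T,C,0.3863
7,T,G,0.2684
8,A,C,0.3077
8,A,G,0.4428
8,A,T,0.3077
8,C,A,0.3077
8,C,G,0.3077
8,C,T,0.4428
8,G,A,0.4428
8,G,C,0.3077
8,G,T,0.3077
8,T,A,0.3077
8,T,C,0.4428
8,T,G,0.3077
9,A,C,0.347
9,A,G,0.4993
9,A,T,0.347
9,C,A,0.347
9,C,G,0.347
9,C,T,0.4993
9,G,A,0.4993
9,G,C,0.347
9,G,T,0.347
9,T,A,0.347
9,T,C,0.4993
9,T,G,0.347
10,A,C,0.3863
10,A,G,0.5558
10,A,T,0.3863
10,C,A,0.3863
10,C,G,0.3863
10,C,T,0.5558
10,G,A,0.5558
10,G,C,0.3863
10,G,T,0.3863
10,T,A,0.3863
10,T,C,0.5558
10,T,G,0.3863
11,A,C,0.4255
11,A,G,0.6124
11,A,T,0.4255
11,C,A,0.4255
11,C,G,0.4255
11,C,T,0.6124
11,G,A,0.6124
11,G,C,0.4255
11,G,T,0.4255
11,T,A,0.4255
11,T,C,0.6124
11,T,G,0.4255
12,A,C,0.4648
12,A,G,0.6689
12,A,T,0.4648
12,C,A,0.4648
12,C,G,0.4648
12,C,T,0.6689
12,G,A,0.6689
12,G,C,0.4648
12,G,T,0.4648
12,T,A,0.4648
12,T,C,0.6689
12,T,G,0.4648
13,A,C,0.5041
13,A,G,0.7254
13,A,T,0.5041
13,C,A,0.5041
13,C,G,0.5041
13,C,T,0.7254
13,G,A,0.7254
13,G,C,0.5041
13,G,T,0.5041
13,T,A,0.5041
13,T,C,0.7254
13,T,G,0.5041
14,A,C,0.5434
14,A,G,0.7819
14,A,T,0.5434
14,C,A,0.5434
14,C,G,0.5434
14,C,T,0.7819
14,G,A,0.7819
14,G,C,0.5434
14,G,T,0.5434
14,T,A,0.5434
14,T,C,0.7819
14,T,G,0.5434
15,A,C,0.5826
15,A,G,0.8384
15,A,T,0.5826
15,C,A,0.5826
15,C,G,0.5826
15,C,T,0.8384
15,G,A,0.8384
15,G,C,0.5826
15,G,T,0.5826
15,T,A,0.5826
15,T,C,0.8384
15,T,G,0.5826
16,A,C,0.6219
16,A,G,0.8949
16,A,T,0.6219
16,C,A,0.6219
16,C,G,0.6219
16,C,T,0.8949
16,G,A,0.8949
16,G,C,0.6219
16,G,T,0.6219
16,T,A,0.6219
16,T,C,0.8949
16,T,G,0.6219
17,A,C,0.6612
17,A,G,0.9515
17,A,T,0.6612
17,C,A,0.6612
17,C,G,0.6612
17,C,T,0.9515
17,G,A,0.9515
17,G,C,0.6612
17,G,T,0.6612
17,T,A,0.6612
17,T,C,0.9515
17,T,G,0.6612
18,A,C,0.7005
18,A,G,1.0
18,A,T,0.7005
18,C,A,0.7005
18,C,G,0.7005
18,C,T,1.0
18,G,A,1.0
18,G,C,0.7005
18,G,T,0.7005
18,T,A,0.7005
18,T,C,1.0
18,T,G,0.7005
19,A,C,0.7397
19,A,G,1.0
19,A,T,0.7397
19,C,A,0.7397
19,C,G,0.7397
19,C,T,1.0
19,G,A,1.0
19,G,C,0.7397
19,G,T,0.7397
19,T,A,0.7397
19,T,C,1.0
19,T,G,0.7397
20,A,C,0.779
20,A,G,1.0
20,A,T,0.779
20,C,A,0.779
20,C,G,0.779
20,C,T,1.0
20,G,A,1.0
20,G,C,0.779
20,G,T,0.779
20,T,A,0.779
20,T,C,1.0
20,T,G,0.779
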