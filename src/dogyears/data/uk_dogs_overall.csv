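x_start,d,a_hat,l
0,514,0.42,30563
1,481,0.52,30049
2,482,0.45,29568
3,489,0.48,29086
4,559,0.48,28597
5,677,0.47,28038
6,892,0.46,27361
7,1254,0.51,26469
8,1730,0.50,25215
9,2265,0.49,23485
10,2852,0.48,21220
11,3449,0.50,18368
12,3645,0.47,14919
13,3785,0.48,11274
14,3126,0.44,7489
15,2249,0.43,4363
16,1253,0.39,2114
17,542,0.38,861
18,218,0.32,319
19,78,0.33,101
20,23,0.46,23
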