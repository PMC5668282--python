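month,raw_count
1,3698
2,3454
3,3846
4,3701
5,3412
6,3466
7,3283
8,3318
9,3154
10,3355
11,3298
12,3420
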