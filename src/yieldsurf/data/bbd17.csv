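std,pH,enzyme_pct,time_min,yield_pct
1,4,1.5,60,10.44
2,6,1.5,60,16.36
3,4,4.5,60,17.68
4,6,4.5,60,20.68
5,4,3,40,8.36
6,6,3,40,25.52
7,4,3,80,10.8
8,6,3,80,21.32
9,5,1.5,40,15.68
10,5,4.5,40,18.04
11,5,1.5,80,23.56
12,5,4.5,80,25.24
13,5,3,60,29.31
14,5,3,60,28.5
15,5,3,60,25.48
16,5,3,60,31
17,5,3,60,23.32
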