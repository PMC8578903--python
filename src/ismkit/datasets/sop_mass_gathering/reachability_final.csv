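,1,2,3,4,5,6,7,8,9,10,11
1,1,1,1,1,1,1,1,1,1,1,1
2,0,1,1,0,1*,1*,1*,1,1,1,1
3,0,1*,1,1*,1*,1,1,1,1,1,1
4,0,1,1,1,1*,1*,1*,1,1,1,1
5,0,1,1,1,1,1*,1,1,1*,1,1
6,0,1,1*,1,1,1,1*,1,1,1*,1
7,1*,1,1*,1,1*,1,1,1,1,1*,1
8,0,0,0,0,0,1*,1*,1,0,1,0
9,0,1*,1*,1*,1,1*,1*,1,1,1,1*
10,0,1*,0,1*,1*,1,1,1*,1*,1,1*
11,0,1*,0,1*,1*,1*,1,1,1,1,1
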