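,1,2,3,4,5,6,7,8,9,10,11
1,,V,V,V,V,V,V,V,V,V,V
2,,,V,A,A,A,A,V,V,V,V
3,,,,A,A,V,V,V,V,V,V
4,,,,,A,A,A,V,V,V,V
5,,,,,,A,V,V,A,V,V
6,,,,,,,A,V,V,A,V
7,,,,,,,,V,V,A,X
8,,,,,,,,,A,V,A
9,,,,,,,,,,V,A
10,,,,,,,,,,,A
11,,,,,,,,,,,
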