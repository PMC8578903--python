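factor_code,label,E1,E2,E3,E4,E5,E6,E7,E8,E9,E10
1,Nature of gathering,1,1,0,1,1,1,1,1,0,1
2,Type of gathering community,1,1,1,1,1,1,1,1,0,1
3,Available physical space at gathering place,1,1,1,1,0,1,1,1,1,1
4,Existence of penal clauses in SOPs,0,1,0,1,0,0,1,1,1,0
5,Campaign of awareness regarding SOPs,1,1,1,1,1,1,1,1,1,1
6,Legal environment of the country,0,1,0,1,1,1,0,1,1,0
7,Practicability of SOPs,1,1,1,1,1,0,1,1,1,1
8,Perceived benefit of adapting SOPs,1,1,1,1,1,0,1,1,1,1
9,Possibilities of implementation of penal clauses,1,1,1,1,1,1,0,1,1,1
10,Possibilities of avoiding gathering,1,1,1,1,1,1,0,1,1,1
11,Seriousness of SOPs implementers,1,1,1,1,1,1,1,1,1,1
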