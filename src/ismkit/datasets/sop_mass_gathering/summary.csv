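code,label,driving,dependence,effectiveness,cluster,level,comment
1,Nature of gathering,11,2,9,Independent,IV,Key factor
2,Type of gathering community,9,10,-1,Linkage,II,
3,Available physical space at gathering place,10,8,2,Linkage,III,
4,Existence of penal clauses in SOPs,10,9,1,Linkage,III,
5,Campaign of awareness regarding SOPs,10,10,0,Linkage,II,
6,Legal environment of the country,10,11,-1,Linkage,I,
7,Practicability of SOPs,11,11,0,Linkage,I,
8,Perceived benefit of adapting SOPs,4,11,-7,Dependent,I,
9,Possibilities of implementation of penal clauses,10,10,0,Linkage,II,
10,Possibilities of avoiding gathering,9,11,-2,Linkage,I,
11,Seriousness of SOPs implementers,9,10,-1,Linkage,II,
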