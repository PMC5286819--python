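# id  rev  stoichiometry  lb  ub
R1  irr  A:1  0  1000
R2  irr  B:1  0  1000
R3  irr  A:1  0  1000
R4  irr  A:-1  0  1000
R5  irr  B:-1,C:1  0  1000
R6  irr  B:-1,D:1  0  1000
R7  irr  C:-1  0  1000
R8  irr  D:-1  0  1000
R9  irr  A:-1,B:1  0  1000
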