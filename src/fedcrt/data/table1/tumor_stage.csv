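category,A,B,C,D
T1,10,11,3,8
T2,32,16,10,21
T3,34,7,11,16
T4,26,8,8,24
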