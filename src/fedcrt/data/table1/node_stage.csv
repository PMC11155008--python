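category,A,B,C,D
N0,16,10,7,20
N1,9,5,6,7
N2,51,13,13,19
N3,26,14,6,23
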