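category,A,B,C,D
M0,66,24,22,32
M1,36,18,10,37
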