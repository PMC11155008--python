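category,A,B,C,D
R,51,31,17,11
nR,51,11,15,58
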