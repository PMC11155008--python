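category,A,B,C,D
LUAD,48,17,14,40
LUSC,54,25,18,29
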