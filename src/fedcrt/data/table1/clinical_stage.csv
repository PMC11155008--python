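category,A,B,C,D
IIIA,26,7,12,12
IIIB,36,14,14,26
IIIC,7,3,2,4
IV,33,18,4,27
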