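category,A,B,C,D
Male,82,34,23,36
Female,20,8,9,33
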