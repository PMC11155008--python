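site,mean,sd,n,min,max
A,64.32,7.81,102,47,81
B,64.21,10.68,42,44,83
C,63.96,8.57,32,39,79
D,68.7,11.4,69,37,91
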