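#miRNA	disease
A	dA
B	dA
C	dB
D	dR
E	dB
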