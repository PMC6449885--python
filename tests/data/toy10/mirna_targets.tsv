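#miRNA	mRNA
A	g1
A	g2
B	g2
B	g3
C	g1
C	g3
C	g4
D	g2
D	g3
E	g2
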