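#disease	tree_number
dR	C01
dA	C01.100
dB	C01.100.200
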