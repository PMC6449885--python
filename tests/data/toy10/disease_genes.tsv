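#disease	gene
dA	h2
dA	h3
dB	h1
dB	h3
dR	h1
dR	h2
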