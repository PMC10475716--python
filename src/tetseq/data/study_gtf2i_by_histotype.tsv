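histotype	n
A	6
AB	5
B2	2
NOS	1
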