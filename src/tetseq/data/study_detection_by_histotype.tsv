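histotype	n_mutated	n_not
A	10	2
AB	8	5
B1	2	3
B2	11	10
B2-B3	1	4
B3	3	10
NOS	3	1
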