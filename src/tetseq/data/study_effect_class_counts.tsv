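effect	n
flank3	0
utr3	6
flank5	0
utr5	2
frameshift_deletion	0
frameshift_insertion	1
inframe_deletion	0
inframe_insertion	0
intergenic	13
intron	132
missense	65
ncRNA	2
nonframeshift_substitution	2
nonsense	1
nonstop	0
splice_site	1
silent	13
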