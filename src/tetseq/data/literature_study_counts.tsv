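study_id	year	n_tets	n_mutations	technology
belani_2014	2014	1	17	whole_genome
enkner_2016	2016	72	27	hotspot_panel_50
wheler_2013	2013	7	4	targeted_182
petrini_2013	2013	1	12	whole_genome
petrini_2014	2014	42	836	whole_exome
shitara_2014	2014	12	25	targeted_409
li_2017	2017	9	137	whole_exome
wang_2014	2014	78	86	targeted_197
radovich_2018	2018	117	3064	whole_exome
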