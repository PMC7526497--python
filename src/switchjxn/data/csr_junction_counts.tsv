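locus	cohort	direct	insertion	mh_1_6	mh_ge7	total
Smu-Salpha	ICF2	4	11	34	33	82
Smu-Salpha	LIG4	1	0	11	18	30
Smu-Salpha	Artemis	0	6	18	30	54
Smu-Salpha	control	34	52	77	50	213
Smu-Sgamma	ICF2	9	3	34	0	46
Smu-Sgamma	LIG4	4	11	19	0	34
Smu-Sgamma	Artemis	5	4	15	0	24
Smu-Sgamma	control	13	9	36	0	58
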