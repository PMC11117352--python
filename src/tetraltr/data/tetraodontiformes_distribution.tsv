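family	Arothron firmamentum	Lagocephalus sceleratus	Mola mola	Pao palembangensis	Takifugu bimaculatus	Takifugu flavidus	Takifugu ocellatus	Takifugu rubripes	Tetraodon nigroviridis	Thamnaconus septentrionalis
Gmr	0	1	0	0	4	3	4	3	0	0
Mag	0	0	0	0	1	1	1	2	0	0
V-clade	1	0	0	3	4	4	3	4	0	0
CsRN1	0	0	0	0	2	2	1	2	1	0
Barthez	0	0	0	0	4	4	3	5	0	1
Epsilon retrovirus	0	0	0	0	3	2	3	2	0	1
Orthoretrovirinae	0	0	1	0	0	0	0	0	0	0
BEL-PAO	0	0	0	0	3	2	3	4	0	0
Copia	0	0	0	0	0	1	0	1	0	1
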