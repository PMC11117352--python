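family	element	copies	full_ltr	gag_n	pol_n	env_n	consensus_bp	ltr_bp	gag_aa	pol_aa	gagpol_aa	env_aa
Gmr	Gmr1	20	16	19	20	0	6465	518			1634
Gmr	Gmr2	6	6	4	6	0	6058	337			1564
Gmr	Gmr3	11	10	9	11	0	6273	412			1506
Gmr	Gmr4	10	9	8	10	0	6223	456			1521
Mag	Mag1	20	18	20	19	0	4696	208			1365
Mag	Mag2	4	4	4	4	0	4813	211			1330
V-clade	V-clade1	55	47	47	55	0	5558	538	371	1119
V-clade	V-clade2	29	25	25	28	0	5226	443	329	890
V-clade	V-clade3	3	3	2	3	0	5346	497	326	822
V-clade	V-clade4	5	3	1	5	0	6444	454	309	1016
V-clade	V-clade5	12	9	11	12	0	5369	328			1281
V-clade	V-clade6	4	3	1	4	0	5430	367	306	801
V-clade	V-clade7	4	4	3	4	0	5264	396	414	1119
CsRN1	CsRN1-1	21	21	0	21	0	4337	174		1061
CsRN1	CsRN1-2	18	17	0	18	0	4552	302		1069
Barthez	Barthez1	13	11	11	13	0	7871	1116	355	1394
Barthez	Barthez2	12	9	8	12	0	7566	1025	359	1339
Barthez	Barthez3	4	2	0	4	0	8756	1114		1563
Barthez	Barthez4	5	5	0	5	0	7513	442		1580
Barthez	Barthez5	17	7	9	17	0	7544	259	526	1580
Barthez	Barthez6	5	4	2	5	0	7310	329	879	1137
BEL-PAO	BEL1	3	3	0	3	0	7624	728		1434
BEL-PAO	BEL2	7	5	0	7	0	6587	536		1808
BEL-PAO	BEL3	10	9	0	9	0	7341	652		1970
BEL-PAO	PAO1	4	3	0	3	0	5939	456		1617
Copia	Copia1	4	4	2	4	0	4794	233	454	653
Orthoretrovirinae	Orthoretrovirinae1	3	3	0	3	0	8626	433		1108
Epsilon retrovirus	Epsilon1	21	19	11	14	9	8630	665	728	776		487
Epsilon retrovirus	Epsilon2	105	93	65	103	40	8158	382	219	951		554
Epsilon retrovirus	Epsilon3	3	2	2	3	0	7880	470	576	740
Epsilon retrovirus	Epsilon4	5	2	4	5	2	9854	377	604	985		477
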