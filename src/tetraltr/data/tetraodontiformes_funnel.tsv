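species	common_name	identified	length_filtered	full_length	assembly	genome_size_mb
Arothron firmamentum	Starry Pufferfish	1224	405	3	GCA_016586285.1	334.905
Lagocephalus sceleratus	Silver-Cheeked Toadfish	3389	35	3	GCA_911728415.1	373.990
Mola mola	Ocean Sunfish	1125	381	63	GCA_001698575.1	639.452
Pao palembangensis	South Sumatran Puffer	1199	365	65	GCA_015343265.1	356.042
Takifugu bimaculatus	Two-Spot Pufferfish	3420	1062	192	GCA_004026145.2	404.312
Takifugu flavidus	Yellow Pufferfish	2783	937	124	GCF_003711565.1	366.303
Takifugu ocellatus	Ocellated Pufferfish	2367	678	117	GCA_027382335.1	375.589
Takifugu rubripes	Tiger Puffer	2757	861	186	GCF_901000725.2	384.127
Tetraodon nigroviridis	Green Spotted Pufferfish	1192	460	24	GCA_000180735.1	342.403
Thamnaconus septentrionalis	Northern Round Herring	2550	979	42	GCA_009823395.1	474.310
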