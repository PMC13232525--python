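allele	sterility_interval	gene	ovo_chip_peak	gsc_atac_peak	st5_nc_atac_peak	insertion_location	motif_distance_nt	left_position	right_position
fs(1)GS01	y-cv	ovo	Yes	Yes	Yes	Intron	135	5064377	5064381
fs(1)GS02	y-cv	arm	No	Yes	No	Intron	1324	1892523	1892528
fs(1)GS02	y-cv	spoon	Yes	Yes	Yes	Intergenic	810	5420873	5420876
fs(1)GS02	y-cv	Rab18	No	Yes	Yes	5'UTR	75	5671746	5671749
fs(1)GS04	cv-v	Sxl	Yes	Yes	Yes	Intron	315	7097886	7097931
fs(1)GS04	cv-v	Intergenic	No	No	No	Intergenic	590	21122630	21122641
fs(1)GS04	cv-v	Intergenic	No	Yes	No	Intergenic	540	22544918	22544921
fs(1)GS05	inconclusive	flam	No	Yes	Yes	Intergenic	1175	21631735	21631737
fs(1)GS08	cv-v	fs(1)M3	Yes	Yes	Yes	Intergenic	85	5964480	5964483
fs(1)GS11	y-cv	VhaAC39-1	No	Yes	Yes	Intron	575	3881217	3881220
fs(1)GS12	v-f	eIF5	No	Yes	No	Intron	340	15991457	15991551
fs(1)GS13	f-	pcm	Yes	Yes	Yes	Intergenic	3750	19492132	19492138
fs(1)GS16	v-f	CG42699	No	No	No	Intron	1190	5776842	5776843
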