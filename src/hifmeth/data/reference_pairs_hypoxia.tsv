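probe_id	gene_id	delta_beta	log2fc	gene_feature	cgi_feature
cg05502283	NFIX	0.22139292	-0.340491	three_prime_UTR	shelf
cg18834544	PCCA	0.20607751	-0.553331	three_prime_UTR	shore
cg12793733	ATP10D	0.2327763	-0.825063	five_prime_UTR	open_sea
cg15524063	ELOVL1	-0.21138562	0.340798	five_prime_UTR	island
cg15883603	SORBS2	0.28146882	-1.01339	five_prime_UTR	open_sea
cg20164964	TSPAN9	0.21253777	-0.411039	five_prime_UTR	open_sea
cg22871175	FAM19A4	0.20371924	-0.80565	five_prime_UTR	open_sea
cg05490591	MSI2	0.21667094	-0.7364	body	open_sea
cg07238439	TPCN1	0.21883677	-0.778461	body	open_sea
cg11197258	NCOR2	0.2523067	-0.583474	body	open_sea
cg13764850	ROR2	0.21935471	-0.372244	body	shelf
cg14377416	VAV2	0.21872117	-0.347793	body	open_sea
cg15570035	ANKRD17	0.20105082	-0.459873	body	open_sea
cg22218512	ACVRL1	0.20924927	-0.735922	body	open_sea
cg26803268	CACNB2	0.2033665	-0.661703	body	open_sea
cg27262041	NAV2	0.21727999	-0.666122	body	open_sea
cg06888900	BCAR1	0.20187808	-0.642616	TSS1500	shore
cg07815799	ARHGEF4	0.27465952	-0.577694	TSS200	island
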