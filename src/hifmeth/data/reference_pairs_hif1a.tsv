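probe_id	gene_id	delta_beta	log2fc	gene_feature	cgi_feature
cg01915791	HSPB6	-0.24969157	0.773186	body	island
cg02836965	SGCZ	-0.21032015	1.47509	body	open_sea
cg03387092	MYLK	-0.22225645	0.588606	body	open_sea
cg03905369	EPB41L5	-0.22872718	1.00335	body	open_sea
cg04056576	PPM1L	-0.22056766	0.857675	body	shore
cg04194674	SRCIN1	0.21094717	-0.865002	body	island
cg06221087	PBX1	-0.20339421	0.535856	body	open_sea
cg08843859	C1orf21	-0.23049642	0.924679	body	open_sea
cg11849717	EGFR	-0.22631862	0.694851	body	island
cg12743970	PRKCA	0.22709241	-0.728741	body	open_sea
cg14862207	SRCIN1	0.20762646	-0.865002	body	island
cg16198315	DACH1	0.21650226	-0.533886	body	shore
cg18277497	FIGN	-0.27273159	0.851071	body	open_sea
cg20897616	GABRB3	-0.24454897	1.42689	body	island
cg21516044	CPE	-0.21441006	0.836739	body	shelf
cg22340526	DPP6	-0.22509589	0.559082	body	shore
cg24597512	GABRB3	-0.21252389	1.42689	body	shore
cg24673955	KIF26B	-0.20727528	0.682105	body	shore
cg25005674	PPP2R2B	-0.24873958	0.895844	body	open_sea
cg26672287	LTBP1	-0.22576329	0.82036	body	open_sea
cg27262041	NAV2	-0.21068975	0.518347	body	open_sea
cg27637738	EGFR	-0.2302424	0.694851	body	open_sea
cg21812277	PARP4	-0.21286384	0.619207	five_prime_UTR	shore
cg08991927	PPP2R2B	-0.21036441	0.895844	five_prime_UTR	shore
cg03690837	ETS2	-0.20969341	0.534019	TSS1500	island
cg11426075	ERRFI1	-0.21603014	0.555979	TSS1500	shore
cg13495205	AJAP1	-0.21926813	0.818246	TSS1500	island
cg18115428	SLC35F3	-0.2429891	1.76376	TSS1500	shore
cg24533917	CHIT1	-0.20768064	2.62046	TSS1500	open_sea
cg26515460	RSPO4	0.21822875	-1.12443	TSS1500	shore
cg09565404	FER	-0.23534751	0.579076	TSS200	shore
cg13072057	B3GALNT1	-0.21923622	0.54531	TSS200	island
cg14135988	RAB27B	-0.20442834	0.713729	TSS200	island
cg14744537	RAB27B	-0.20487652	0.713729	TSS200	island
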