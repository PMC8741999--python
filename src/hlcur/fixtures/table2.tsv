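patient_id	gene	transcript	cdna	protein	consequence	zygosity	dbsnp	af_global	prior_assertion	evidence	reference	phase_partner	phenotype	segregation	after_curation
1	CDH23	NM_022124.5	c.337del	p.(Val113*)	nonsense	het	-	-	-	PM2, PVS1, PM3, PP4	This work	CDH23:c.3353del	Usher syndrome. PL, PR, B, PF, CI	Maternal	Pathogenic
1	CDH23	NM_022124.5	c.3353del	p.(Gly1118Alafs*7)	frameshift	het	-	-	-	PM2, PVS1, PM3, PP4	This work	CDH23:c.337del	Usher syndrome. PL, PR, B, PF, CI	Paternal	Pathogenic
2	MYO6	NM_004999.4	c.1939T>C	p.(Phe647Leu)	missense	het	rs752585373	-	-	PM2, PP3	This work	-	PL, B, M	Non available	VUS
3	EYA4	NM_004100.5	c.580+2T>C	-	splice_site	het	-	-	-	PM2, PVS1, PP1_Sup	This work	-	PL, B, M	Maternal	Pathogenic
4	MYO7A	NM_000260.4	c.733C>T	p.(Gln245*)	nonsense	het	-	-	-	PVS1, PM2, PM3	This work	MYO7A:c.1344-2A>G	C, PL, B, PF, CI	Maternal	Pathogenic
4	MYO7A	NM_000260.4	c.1344-2A>G	-	splice_site	het	rs111033415	-	P	PM2, PVS1, PM3_S, PP4	CR65	MYO7A:c.733C>T	C, PL, B, PF, CI	Paternal	Pathogenic
5	LARS2	NM_015340.3	c.1481dup	p.(Leu495Thrfs*31)	frameshift	het	rs762797278	-	-	PVS1, PM2, PM3, PP1_Sup	This work	LARS2:c.1886C>T	C, B, PF, CI	Paternal	Pathogenic
5	LARS2	NM_015340.3	c.1886C>T	p.Thr629Met	missense	het	rs398123036	-	P	PM2, PM3_S, PP1_Sup, PP4	CR16	LARS2:c.1481dup	C, B, PF, CI	Maternal	LikelyPathogenic
6	ADGRV1	NM_032119.3	c.12829C>T	p.(Arg4277*)	nonsense	het	-	-	-	PVS1, PM2, PM3, PP1_Sup, PP4	This work	ADGRV1:c.956dup	Usher syndrome. B, P, PR	Non available father	Pathogenic
6	ADGRV1	NM_032119.3	c.956dup	p.(Asn319Lysfs*6)	frameshift	het	rs752179149	-	P	PVS1, PM2, PM3, PP1_Sup, PP4	CR66	ADGRV1:c.12829C>T	Usher syndrome. B, P, PR	Maternal	Pathogenic
7	MITF	NM_000248.3	c.877C>T	p.(Arg293*)	nonsense	het	-	-	-	PM2, PVS1_S, PP1_S	CR15	-	C, B, PF, CI	Segregation confirmed	Pathogenic
8	TMPRSS3	NM_024022.3	c.1276G>A	p.Ala426Thr	missense	het	rs56264519	-	P/LP	BS1_Sup, PM3_VS, PP1_S, PS3_Sup	CR67	TMPRSS3:c.242C>G	PL, B, sloping audiometry	Maternal inheritance	Pathogenic
8	TMPRSS3	NM_024022.3	c.242C>G	p.(Ser81*)	nonsense	het	rs757110501	-	-	PVS1, PM2, PM3, PP1_Sup	This work	TMPRSS3:c.1276G>A	PL, B, sloping audiometry	Paternal inheritance	Pathogenic
9	WFS1	NM_006005.3	c.2590G>A	p.(Glu864Lys)	missense	het	rs74315205	-	P/LP	PM2, PS4_M, PP1_Mod, PP3	CR68	-	B, CI	-	LikelyPathogenic
10	USH2A	NM_206933.4	c.1841-2A>G	-	splice_site	het	rs397518003	-	P	PM2, PM3_VS, PP4, PP1_M, PS3_S	CR69	USH2A:c.10712C>T	PR, B, M. No retinopathies	Maternal inheritance	Pathogenic
10	USH2A	NM_206933.4	c.10712C>T	p.(Thr3571Met)	missense	het	rs202175091	-	P/LP	PM2, PM3_VS, PP4, PP1_M	CR70	USH2A:c.1841-2A>G	PR, B, M. No retinopathies	Paternal inheritance	Pathogenic
11	CDH23	NM_022124.5	c.1096G>A	p.(Ala366Thr)	missense	het	rs143282422	-	B	BA1	CR71	CDH23:c.1515-12G>A	B, High-frequency affected. No retinopathies	Maternal	Benign
11	CDH23	NM_022124.5	c.1515-12G>A	-	splice_site	het	rs369396703	-	VUS	PM2_Sup, PM3, PP1_Sup, PP3, PP4	-	CDH23:c.1096G>A	B, High-frequency affected. No retinopathies	Paternal	LikelyPathogenic
12	COL4A3	NM_000091.5	c.3500G>A	p.(Gly1167Glu)	missense	het	-	-	-	PM2, PS2, PM1, PM5, PP3	This work	-	Alport Syndrome. Hematuria	De novo (maternal)	Pathogenic
12	COL4A3	NM_000091.5	c.4649T>G	p.(Val1550Gly)	missense	het	rs200655479	-	ConflictingInterpretation	PM2_Sup, PP3	CR72	-	Alport Syndrome. Hematuria	-	VUS
13	DFNA5	NM_004403.2	c.119dup	p.(Lys41Glufs*113)	frameshift	het	rs758488919	-	ConflictingInterpretation	BA1, PS2	-	-	No familial history	De novo	Benign
14	COL4A5	NM_000495.3	c.1183C>T	p.(Pro395Ser)	missense	het	-	-	-	PM2	This work	-	C, B, S	-	VUS
15	COL4A5	NM_000495.3	c.1759C>T	p.(Pro587Ser)	missense	het	-	-	-	PM2, PP3	This work	-	PL, PR, B, M	-	VUS
16	COL4A5	NM_000495.3	c.3659G>A	p.(Gly1220Asp)	missense	het	rs104886251	-	P	PM2, PM1, PP3, PP4, PS4_Sup	CR73	-	Alport Syndrome. Hematuria	-	Pathogenic
17	WFS1	NM_006005.3	c.2327A>T	p.(Glu776Val)	missense	het	rs56002719	-	ConflictingInterpretation	BA1, PP3, PP1_Sup, BS4	CR74	-	B, M, PR. High frequencies	Maternal inheritance	Benign
18	TECTA	NM_005422.4	c.5668C>T	p.(Arg1890Cys)	missense	het	rs121909063	-	LP	PM2, PP1_VS, PS4_Sup	CR75	-	PL, M-S	Segregation confirmed. Paternal inheritance	Pathogenic
19	LOXHD1	NM_144612.6	c.4480C>T	p.(Arg1494*)	nonsense	hom	rs201587138	-	P/LP	PVS1, BS1_Sup, PM3_S, PP1_M	CR76	-	C, B, PF	Segregation confirmed	Pathogenic
20	ACTG1	NM_001614.5	c.353A>T	p.(Lys118Met)	missense	het	rs104894544	-	LP	PS4_Sup, PM2, PP5, PP1_S, PP3	CR77	-	PL, B, M-S	Segregation confirmed. Paternal inheritance	Pathogenic
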