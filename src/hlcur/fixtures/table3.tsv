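patient_id	gene	transcript	cdna	protein	consequence	zygosity	evidence	classification	effect_printed	mechanism_label	ddg_mean	ddg_sd	interface	helix	exposed	clinvar	dvd_lovd	reference
LARS2-DB	LARS2	NM_015340.3	c.351G>C	p.(Met117Ile)	missense	het	PM2, PM3, PP1, PP4, PP3	LikelyPathogenic	Stability	stability	4.11	0.63	0	1	-	-	P/LP	PMID:26970254
LARS2-DB	LARS2	NM_015340.3	c.371A>T	p.(Asn124Ile)	missense	het	PM2, PM3_Strong, PP4	LikelyPathogenic	Non conclusive	nonconclusive	0.41	0.66	0	0	-	P	P/-	PMID:28708303
LARS2-DB	LARS2	NM_015340.3	c.440A>C	p.(Gln147Pro)	missense	het	PM2, PM3, PP4, BP4_Supporting, PP3	LikelyPathogenic	Stability	stability	1.49	0.12	0	1	-	LP	LP/-	SCV000994657.1
LARS2-DB	LARS2	NM_015340.3	c.457A>C	p.(Asn153His)	missense	het	PM2, PM3, PP3, PP4	LikelyPathogenic	Stability	stability	3.36	0.82	0	1	-	LP	LP/-	PMID:32423379
LARS2-DB	LARS2	NM_015340.3	c.683G>A	p.(Arg228His)	missense	het	PM2, PM3_Supporting, PP3, PP4	LikelyPathogenic	Electrostatic Surface	electrostatic_surface	0.40	0.02	0	0	1	LP	LP/LP	PMID:28000701
LARS2-DB	LARS2	NM_015340.3	c.880G>A	p.(Glu294Lys)	missense	het	PM2, PM3_Strong, PP4, PP3	LikelyPathogenic	Electrostatic surface	electrostatic_surface	0.67	0.14	0	0	1	-	P/LP	PMID:28000701
LARS2-DB	LARS2	NM_015340.3	c.899C>T	p.(Thr300Met)	missense	het	PM2, PM3, PP1, PP3, PP4	LikelyPathogenic	tRNA interaction	interface_interaction	0.12	0.84	1	0	-	P	P/P	PMID:26657938
LARS2-DB	LARS2	NM_015340.3	c.1077del	p.Ile360fs	frameshift	het	PVS1, PS3_Supporting, PM2, PM3, PP4	Pathogenic	LoF	LoF	-	-	0	0	-	P	P/P	PMID:23541342
LARS2-DB	LARS2	NM_015340.3	c.1115C>G	p.(Ser372*)	nonsense	het	PVS1, PM2, PP4	Pathogenic	LoF	LoF	-	-	0	0	-	LP	LP/-	SCV000891207.1
LARS2-DB	LARS2	NM_015340.3	c.1237G>A	p.(Glu413Lys)	missense	het	PM2, BP4, PP4	VUS	Electrostatic surface	electrostatic_surface	0.14	0.02	0	0	1	LP	LP/-	SCV001244305.1
LARS2-DB	LARS2	NM_015340.3	c.1358G>A	p.(Arg453Gln)	missense	het	PM2_Supporting, PM3, PP3, PP4	LikelyPathogenic	Electrostatic surface/Stability?	nonconclusive	1.42	0.3	0	0	0	-	P/P	PMID:27650058
LARS2-DB	LARS2	NM_015340.3	c.1481dup	p.(Leu495fs)	frameshift	het	PVS1, PM2, PM3, PP1_Supporting	Pathogenic	LoF	LoF	-	-	0	0	-	-	P/-	This study paper
LARS2-DB	LARS2	NM_015340.3	c.1520C>G	p.(Pro507Arg)	missense	het	PM2, PM3, PP1_Supporting, PP3	LikelyPathogenic	Stability	stability	2.20	0.07	0	0	0	LP	LP/-	SCV000731430.1
LARS2-DB	LARS2	NM_015340.3	c.1556C>T	p.(Thr519Met)	missense	het	PM2, PM3, PP1_Supporting, PP3, PP4	LikelyPathogenic	&	nonconclusive	-0.44	0.25	0	0	0	-	P/-	PMID:29205794
LARS2-DB	LARS2	NM_015340.3	c.1565C>A	p.Thr522Asn	missense	het	PM2_Supporting, PM3_Strong, PS3_Supporting, PP3, PP4	LikelyPathogenic	&	nonconclusive	-0.59	0.08	0	0	0	LP	P/LP	PMID:23541342
LARS2-DB	LARS2	NM_015340.3	c.1607C>T	p.(Pro536Leu)	missense	het	PM2, PS3_Supporting, PM3, PP3, PP4	LikelyPathogenic	Stability	stability	6.82	1.87	0	1	-	LP	LP/-	SCV000994658.1
LARS2-DB	LARS2	NM_015340.3	c.1886C>T	p.Thr629Met	missense	het	PM2, PM3_Strong, PP1_Sup, PP4	LikelyPathogenic	Stability	stability	2.56	0.19	0	0	-	P	P/P	PMID:23541342
LARS2-DB	LARS2	NM_015340.3	c.1912G>A	p.(Glu638Lys)	missense	het	PM2, PM3, PP1_Supporting, PP3, PP4	LikelyPathogenic	tRNA interaction	interface_interaction	-0.06	0.50	1	0	-	P	P/P	PMID:26657938
LARS2-DB	LARS2	NM_015340.3	c.1987C>T	p.(Arg663Trp)	missense	het	PM2, PS3_Supporting, PM3_Strong, PP3, PP4	LikelyPathogenic	Stability	stability	2.94	0.32	0	0	0	P	P/-	PMID:28708303
LARS2-DB	LARS2	NM_015340.3	c.2108T>C	p.(Ile703Thr)	missense	het	PM2, PM3, PP3, PP4	LikelyPathogenic	tRNA interaction	interface_interaction	0.67	0.11	1	0	-	-	LP/-	PMID:32767731
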