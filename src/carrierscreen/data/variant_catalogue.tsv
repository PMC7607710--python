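variant_id	gene	transcript	chgvs	phgvs	filter_status	depth	af_1000G	af_gnomAD_SAS	evidence	novel	subcontinent	occurrences
SLC26A4:c.1001G>T	SLC26A4	ENST00000265715	c.1001G>T	p.Gly334Val	PASS	62	0.0002		PS3 + PM2 + PP2 + PP3 + PP4 + PP5	false	false	2
SLC26A4:c.1226G>C	SLC26A4	ENST00000265715	c.1226G>C	p.Arg409Pro	PASS	58	0.0004	0.0012	PM2 + PM5 + PP2 + PP3 + PP5	false	true	1
SLC26A4:c.1468A>C	SLC26A4	ENST00000265715	c.1468A>C	p.Ile490Leu	PASS	71	0.0003	0.0009	PS1 + PM1 + PP2 + PP3 + PP5	false	true	1
SLC26A4:c.1003T>C	SLC26A4	ENST00000265715	c.1003T>C	p.Phe335Leu	PASS	66	0.0008		PS1 + PP2 + PP3 + PP5	false	false	1
GJB2:c.231G>A	GJB2	ENST00000382844	c.231G>A	p.Trp77Ter	PASS	84	0.0005	0.0016	PVS1 + PS3 + PM1 + PM4 + PP2 + PP3	false	true	2
GJB2:c.71G>A	GJB2	ENST00000382844	c.71G>A	p.Trp24Ter	PASS	92	0.0011	0.0031	PVS1 + PS3 + PM1 + PM4 + PP2 + PP3	false	true	1
TMPRSS3:c.413C>A	TMPRSS3	ENST00000291532	c.413C>A	p.Ala138Glu	PASS	54	0.0002		PM1 + PM2 + PP2 + PP3	false	false	1
TMPRSS3:c.323-6G>A	TMPRSS3	ENST00000291532	c.323-6G>A		PASS	47	0.0003	0.0011	PS3 + PS4 + PM2 + PP3	false	true	2
TMC1:c.1165C>T	TMC1	ENST00000297784	c.1165C>T	p.Arg389Ter	PASS	60	0.0001		PVS1 + PS3 + PM2 + PM4 + PP3	false	false	1
CFTR:c.223C>T	CFTR	ENST00000003084	c.223C>T	p.Arg75Ter	PASS	75	0.0002		PVS1 + PS3 + PM2 + PM4 + PP2 + PP3	false	false	1
CFTR:c.1646G>A	CFTR	ENST00000003084	c.1646G>A	p.Ser549Asn	PASS	69	0.0002	0.0008	PS3 + PM1 + PM2 + PM5 + PP2 + PP3 + PP5	false	true	1
CFTR:c.595C>T	CFTR	ENST00000003084	c.595C>T	p.His199Tyr	PASS	57	0.0001		PS3 + PM1 + PM2 + PM5 + PP2 + PP3 + PP5	false	false	1
CFTR:c.3209G>A	CFTR	ENST00000003084	c.3209G>A	p.Arg1070Gln	PASS	63	0.0003		PS3 + PM1 + PM5 + PP2 + PP3 + PP5	false	false	1
CFTR:p.Phe508del	CFTR	ENST00000003084		p.Phe508del	PASS	81	0.0040		PS3 + PM1 + PM4 + PP2 + PP3	false	false	1
CFTR:c.4096A>T	CFTR	ENST00000003084	c.4096A>T	p.Ile1366Phe	PASS	52	0.0001		PM1 + PM2 + PP2 + PP3	false	false	1
CFTR:c.1472G>T	CFTR	ENST00000003084	c.1472G>T	p.Cys491Phe	PASS	49	0.0001		PM1 + PM2 + PP2 + PP3	false	false	1
CFTR:c.4009T>G	CFTR	ENST00000003084	c.4009T>G	p.Phe1337Val	PASS	55	0.0002		PM1 + PM2 + PP2 + PP3	false	false	1
CFTR:c.1859A>T	CFTR	ENST00000003084	c.1859A>T	p.His620Leu	PASS	59	0.0001		PM1 + PM2 + PM5 + PP2 + PP3	false	false	1
GAA:c.1933G>A	GAA	ENST00000302262	c.1933G>A	p.Asp645Asn	PASS	72	0.0006		PS4 + PM1 + PM2 + PM5 + PP2 + PP3 + PP5	false	false	3
MMAA:c.433C>T	MMAA	ENST00000281317	c.433C>T	p.Arg145Ter	PASS	67	0.0002		PVS1 + PS3 + PM4 + PP2 + PP3	false	false	2
COL7A1:c.5287C>T	COL7A1	ENST00000328333	c.5287C>T	p.Arg1763Ter	PASS	44	0.0001		PVS1 + PM1 + PM4 + PP2	false	false	1
GALT:c.563A>G	GALT	ENST00000378842	c.563A>G	p.Gln188Arg	PASS	78	0.0021		PS3 + PM1 + PP2 + PP3 + PP4 + PP5	false	false	2
DHCR7:c.730G>A	DHCR7	ENST00000355527	c.730G>A	p.Gly244Arg	PASS	61	0.0001		PS1 + PM2 + PP2 + PP3 + PP4 + PP5	false	false	1
DHCR7:c.862G>A	DHCR7	ENST00000355527	c.862G>A	p.Glu288Lys	PASS	58	0.0002		PM2 + PP1 + PP2 + PP3 + PP4 + PP5	false	false	1
BTD:c.469C>T	BTD	ENST00000303498	c.469C>T	p.Arg157Cys	PASS	73	0.0003		PS3 + PM1 + PM2 + PM5 + PP2 + PP3	false	false	1
ACADM:c.811G>A	ACADM	ENST00000420607	c.811G>A	p.Gly271Arg	PASS	68	0.0004		PS1 + PS3 + PP2 + PP3 + PP5	false	false	1
LAMB3:c.2138-2A>G	LAMB3	ENST00000391911	c.2138-2A>G		PASS	51			PVS1 + PM2 + PP3	true	false	2
ARSA:c.1210+1G>T	ARSA	ENST00000216124	c.1210+1G>T		PASS	46			PVS1 + PM2 + PP3 + PP5	true	false	1
PEX1:c.2926+2T>C	PEX1	ENST00000248633	c.2926+2T>C		PASS	53	0.0001		PVS1 + PM2 + PP3 + PP5	false	false	1
PKHD1:c.8441-1G>C	PKHD1	ENST00000371117	c.8441-1G>C		PASS	42			PVS1 + PM2 + PP3	true	false	1
PKHD1:c.1480C>T	PKHD1	ENST00000371117	c.1480C>T	p.Arg494Ter	PASS	64	0.0002		PVS1 + PS3 + PM2 + PM4 + PP2	false	false	1
OCA2:c.1580T>G	OCA2	ENST00000354638	c.1580T>G	p.Leu527Arg	PASS	70	0.0005	0.0018	PM2 + PP2 + PP3 + PP4 + PP5	false	true	2
PAH:c.688G>A	PAH	ENST00000553106	c.688G>A	p.Val230Ile	PASS	66	0.0009		PS4 + PM1 + PP2 + PP3 + PP5	false	false	2
CAPN3:c.1504A>G	CAPN3	ENST00000397163	c.1504A>G	p.Ile502Val	PASS	59	0.0001		PM1 + PM2 + PM5 + PP2 + PP3	false	false	1
CYP21A2:c.373C>T	CYP21A2	ENST00000418967	c.373C>T	p.Arg125Cys	PASS	38	0.0002		PM2 + PP2 + PP3 + PP4 + PP5	false	false	1
MLC1:c.65G>A	MLC1	ENST00000311597	c.65G>A	p.Arg22Gln	PASS	77	0.0012		PS3 + PP2 + PP3 + PP4	false	false	1
MLC1:c.959C>A	MLC1	ENST00000311597	c.959C>A	p.Thr320Lys	PASS	74	0.0001		PS3 + PM2 + PP2 + PP3 + PP5	false	false	1
AGXT:c.302T>C	AGXT	ENST00000307503	c.302T>C	p.Leu101Pro	PASS	62	0.0003	0.0014	PS3 + PM2 + PP2 + PP3	false	true	1
GBA:c.866G>C	GBA	ENST00000327247	c.866G>C	p.Gly289Ala	PASS	56	0.0001	0.0007	PM2 + PP2 + PP3 + PP4 + PP5	false	true	1
GBA:c.1448T>C	GBA	ENST00000327247	c.1448T>C	p.Leu483Pro	PASS	65	0.0006	0.0021	PS3 + PM5 + PP2 + PP3 + PP5	false	true	1
ASL:c.857A>G	ASL	ENST00000304874	c.857A>G	p.Gln286Arg	PASS	69	0.0004		PS4 + PP2 + PP3 + PP5	false	false	1
ASPA:c.902T>C	ASPA	ENST00000263080	c.902T>C	p.Leu301Pro	PASS	60	0.0002	0.0010	PM2 + PP2 + PP3 + PP4 + PP5	false	true	1
GCDH:c.281G>A	GCDH	ENST00000222214	c.281G>A	p.Arg94Gln	PASS	58	0.0003	0.0013	PM2 + PM5 + PP2 + PP3 + PP4 + PP5	false	true	1
GALC:c.956A>G	GALC	ENST00000261304	c.956A>G	p.Tyr319Cys	PASS	55	0.0002	0.0008	PM1 + PM2 + PM5 + PP2 + PP3	false	true	1
TGM1:c.550C>T	TGM1	ENST00000206765	c.550C>T	p.Pro184Ser	PASS	63	0.0001		PM2 + PM3 + PP2 + PP3 + PP5	false	false	1
ACADVL:c.1480T>C	ACADVL	ENST00000543245	c.1480T>C	p.Phe494Leu	PASS	57	0.0002		PM1 + PM2 + PP2 + PP3	false	false	1
NPC1:c.3560C>T	NPC1	ENST00000269228	c.3560C>T	p.Ala1187Val	PASS	61	0.0001		PM5 + PP2 + PP3 + PP4 + PP5	false	false	1
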