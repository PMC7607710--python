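symbol	transcript	disorder_name	omim_id	inheritance
CFTR	ENST00000003084	Cystic fibrosis	219700	AR
SLC26A4	ENST00000265715	Deafness, AR 4, with enlarged vestibular aqueduct	274600	AR
GJB2	ENST00000382844	Deafness, AR 1A	220290	AR
TMPRSS3	ENST00000291532	Deafness, AR 8	601072	AR
TMC1	ENST00000297784	Deafness, AR 7	600974	AR
GAA	ENST00000302262	Glycogen storage disease II (Pompe disease)	232300	AR
MMAA	ENST00000281317	Methylmalonic aciduria, cblA type	251100	AR
PKHD1	ENST00000371117	Polycystic kidney disease, AR	263200	AR
GALT	ENST00000378842	Galactosemia	230400	AR
DHCR7	ENST00000355527	Smith-Lemli-Opitz syndrome	270400	AR
OCA2	ENST00000354638	Oculocutaneous albinism type II	203200	AR
MLC1	ENST00000311597	Megalencephalic leukoencephalopathy with subcortical cysts	604004	AR
GBA	ENST00000327247	Gaucher disease	230800	AR
PAH	ENST00000553106	Phenylketonuria	261600	AR
LAMB3	ENST00000391911	Junctional epidermolysis bullosa	226650	AR
LAMC2	ENST00000900100	Junctional epidermolysis bullosa	226700	AR
NPC1	ENST00000269228	Niemann-Pick disease type C1	257220	AR
BTD	ENST00000303498	Biotinidase deficiency	253260	AR
ACADM	ENST00000420607	Medium-chain acyl-CoA dehydrogenase deficiency	201450	AR
CAPN3	ENST00000397163	Limb-girdle muscular dystrophy type 2A (calpainopathy)	253600	AR
CYP21A2	ENST00000418967	Congenital adrenal hyperplasia	201910	AR
AGXT	ENST00000307503	Primary hyperoxaluria type 1	259900	AR
ASL	ENST00000304874	Argininosuccinic aciduria	207900	AR
ASPA	ENST00000263080	Canavan disease	271900	AR
GCDH	ENST00000222214	Glutaric aciduria type 1	231670	AR
GALC	ENST00000261304	Krabbe disease	245200	AR
TGM1	ENST00000206765	Congenital ichthyosis, AR 1	242300	AR
ARSA	ENST00000216124	Metachromatic leukodystrophy	250100	AR
PEX1	ENST00000248633	Zellweger syndrome	214100	AR
COL7A1	ENST00000328333	Epidermolysis bullosa dystrophica, AR	226600	AR
ACADVL	ENST00000543245	Very long chain acyl-CoA dehydrogenase deficiency	201475	AR
HEXA	ENST00000900001	Tay-Sachs disease	900001	AR
SMPD1	ENST00000900002	Niemann-Pick disease type A/B	900002	AR
ATP7B	ENST00000900003	Wilson disease	900003	AR
MMUT	ENST00000900004	Methylmalonic aciduria, mut type	900004	AR
PCCA	ENST00000900005	Propionic acidemia (PCCA)	900005	AR
PCCB	ENST00000900006	Propionic acidemia (PCCB)	900006	AR
IVD	ENST00000900007	Isovaleric acidemia	900007	AR
MCCC1	ENST00000900008	3-methylcrotonyl-CoA carboxylase deficiency 1	900008	AR
MCCC2	ENST00000900009	3-methylcrotonyl-CoA carboxylase deficiency 2	900009	AR
FAH	ENST00000900010	Tyrosinemia type I	900010	AR
G6PC1	ENST00000900011	Glycogen storage disease Ia	900011	AR
AGL	ENST00000900012	Glycogen storage disease III	900012	AR
NPC2	ENST00000900013	Niemann-Pick disease type C2	900013	AR
IDUA	ENST00000900014	Mucopolysaccharidosis type I	900014	AR
ARSB	ENST00000900015	Mucopolysaccharidosis type VI	900015	AR
GUSB	ENST00000900016	Mucopolysaccharidosis type VII	900016	AR
GNPTAB	ENST00000900017	Mucolipidosis II/III	900017	AR
MCOLN1	ENST00000900018	Mucolipidosis IV	900018	AR
CTNS	ENST00000900019	Nephropathic cystinosis	900019	AR
SLC22A5	ENST00000900020	Primary carnitine deficiency	900020	AR
ETFA	ENST00000900021	Glutaric acidemia IIA	900021	AR
ETFB	ENST00000900022	Glutaric acidemia IIB	900022	AR
ETFDH	ENST00000900023	Glutaric acidemia IIC	900023	AR
HADHA	ENST00000900024	LCHAD deficiency	900024	AR
HADHB	ENST00000900025	Trifunctional protein deficiency	900025	AR
CPT2	ENST00000900026	Carnitine palmitoyltransferase II deficiency	900026	AR
ASS1	ENST00000900027	Citrullinemia type I	900027	AR
CBS	ENST00000900028	Homocystinuria	900028	AR
OTOF	ENST00000900029	Deafness, AR 9	900029	AR
USH2A	ENST00000900030	Usher syndrome type IIA	900030	AR
CDH23	ENST00000900031	Usher syndrome type ID	900031	AR
PCDH15	ENST00000900032	Usher syndrome type IF	900032	AR
SGCA	ENST00000900033	Limb-girdle muscular dystrophy type 2D	900033	AR
SGCB	ENST00000900034	Limb-girdle muscular dystrophy type 2E	900034	AR
SGCG	ENST00000900035	Limb-girdle muscular dystrophy type 2C	900035	AR
FKRP	ENST00000900036	Limb-girdle muscular dystrophy type 2I	900036	AR
LAMA2	ENST00000900037	Congenital muscular dystrophy (merosin-deficient)	900037	AR
TPP1	ENST00000900038	Neuronal ceroid lipofuscinosis 2	900038	AR
PPT1	ENST00000900039	Neuronal ceroid lipofuscinosis 1	900039	AR
ALDOB	ENST00000900040	Hereditary fructose intolerance	900040	AR
CLN3	ENST00000900041	Neuronal ceroid lipofuscinosis 3	900041	AR
GLA	ENST00000900042	Fabry disease	900042	XL
OTC	ENST00000900043	Ornithine transcarbamylase deficiency	900043	XL
F8	ENST00000900044	Hemophilia A	900044	XL
F9	ENST00000900045	Hemophilia B	900045	XL
IDS	ENST00000900046	Hunter syndrome (MPS II)	900046	XL
IL2RG	ENST00000900047	Severe combined immunodeficiency, X-linked	900047	XL
ABCD1	ENST00000900048	Adrenoleukodystrophy	900048	XL
LDLR	ENST00000900049	Familial hypercholesterolemia	900049	AD_AR
APOB	ENST00000900050	Familial hypercholesterolemia type B	900050	AD_AR
PCSK9	ENST00000900051	Familial hypercholesterolemia 3	900051	AD_AR
RYR1	ENST00000900052	RYR1-related myopathy	900052	AD_AR
WFS1	ENST00000900053	Wolfram syndrome / WFS1-related deafness	900053	AD_AR
TECTA	ENST00000900054	TECTA-related deafness	900054	AD_AR
COL11A2	ENST00000900055	COL11A2-related deafness	900055	AD_AR
MYO6	ENST00000900056	MYO6-related deafness	900056	AD_AR
GJB6	ENST00000900057	GJB6-related deafness	900057	AD_AR
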