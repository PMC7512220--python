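gi_accession	protein_name	gene_name	p_value	log10_fc	fold_change	direction
148727341	Serine-threonine kinase receptor-associated protein	STRAP	0.00019	0.21	1.6	increased
122538467	Proteasome subunit beta type-4	PSMB4	0.00021	0.25	1.77	increased
24371248	FUN14 domain-containing protein 2	FUNDC2	0.00048	0.25	1.80	increased
41281564	WD repeat-containing protein 37	WDR37	0.00049	0.23	1.69	increased
145275202	Isoaspartyl peptidase/l-asparaginase	ASRGL1	0.00050	0.21	1.61	increased
148539872	Acetyl-CoA acetyltransferase, cytosolic	ACAT2	0.00072	0.21	1.62	increased
7705558	Inositol-3-phosphate synthase 1	ISYNA1	0.0011	0.24	1.75	increased
7019419	Nucleolar GTP-binding protein 2	GNL2	0.0013	0.38	2.38	increased
4503165	cullin-3	CUL3	0.0014	0.45	2.80	increased
44680136	d-beta-hydroxybutyrate dehydrogenase, mitochondrial	BDH1	0.0014	0.41	2.60	increased
4502205	ADP-ribosylation factor 4	ARF4	0.0019	0.27	1.86	increased
259155315	Mitochondrial 2-oxoglutarate/malate carrier protein	SLC25A11	0.0022	0.24	1.73	increased
13129110	Methylosome protein 50	WDR77	0.0023	0.24	1.75	increased
4506923	SH2 domain-containing protein 1A	SH2D1A	0.0023	0.28	1.90	increased
6912388	Grancalcin	GCA	0.0024	0.25	1.79	increased
115270970	Chloride channel CLIC-like protein 1	CLCC1	0.0024	0.24	1.74	increased
5031981	26S proteasome non-ATPase regulatory subunit 14	PSMD14	0.0029	0.32	2.09	increased
188219591	Nucleolysin TIA-1 isoform p40	TIA1	0.0030	0.27	1.85	increased
22035672	Thioredoxin reductase 2, mitochondrial	TXNRD2	0.0031	0.34	2.18	increased
5454166	Vesicle transport through interaction with t-SNAREs homolog 1B	VTI1B	0.0033	0.29	1.93	increased
7657116	Glyceraldehyde-3-phosphate dehydrogenase, testis-specific	GAPDHS	0.0033	0.35	2.23	increased
225543288	SUMO-activating enzyme subunit	SAE1	0.0035	0.25	1.80	increased
47132595	Phosphate carrier protein, mitochondrial	SLC25A3	0.0036	0.32	2.09	increased
28373194	Proteasomal ubiquitin receptor ADRM1	ADRM1	0.0040	0.43	2.69	increased
153251272	Calcineurin-like phosphoesterase domain-containing protein 1	CPPED1	0.0041	0.21	1.61	increased
4505023	Proteasome assembly chaperone 1	PSMG1	0.0050	0.49	3.09	increased
300360515	Actin-related protein 2/3 complex subunit 1A	ARPC1A	0.0051	0.23	1.71	increased
183396804	Regulation of nuclear pre-mRNA domain-containing protein 2	RPRD2	0.0056	0.35	2.26	increased
4885375	Histone H1.2	H1-2	0.0058	0.25	1.79	increased
48762926	Periodic tryptophan protein 2 homolog	PWP2	0.0064	0.36	2.30	increased
4885373	Histone H1.1	H1-1	0.0065	0.29	1.95	increased
4885379	Histone H1.4	H1-4	0.0068	0.24	1.74	increased
5032087	Splicing factor 3A subunit 1 isoform 1	SF3A1	0.0069	0.20	1.59	increased
15487670	Nuclear RNA export factor 1 isoform 1	NXF1	0.0073	0.21	1.61	increased
4885377	Histone H1.3	H1-3	0.0073	0.26	1.83	increased
330340389	Up-regulated during skeletal muscle growth protein 5	USMG5	0.0088	0.23	1.70	increased
4506741	40S ribosomal protein S7	RPS7	0.0090	0.23	1.69	increased
4885381	Histone H1.5	H1-5	0.0095	0.29	1.94	increased
7706495	dnaJ homolog subfamily B member 11	DNAJB11	0.00032	-0.24	0.57	decreased
4557367	Bleomycin hydrolase	BLMH	0.00045	-0.36	0.43	decreased
34101286	Zinc finger RNA-binding protein	ZFR	0.00047	-0.28	0.52	decreased
14149916	src-like-adapter 2	SLA2	0.00054	-0.23	0.58	decreased
66933005	Calnexin	CANX	0.0012	-0.24	0.58	decreased
6715607	Hemoglobin subunit gamma-2	HBG2	0.0014	-0.51	0.31	decreased
5031977	Nicotinamide phosphoribosyltransferase	NAMPT	0.0014	-0.31	0.49	decreased
8923541	UPF0587 protein C1orf123	C1orf123	0.0017	-0.46	0.35	decreased
10863927	Peptidyl-prolyl cis-trans isomerase A	PPIA	0.0026	-0.26	0.54	decreased
143770741	Platelet glycoprotein VI	GP6	0.0028	-0.21	0.61	decreased
19913385	Protein G6b	C6orf25	0.0038	-0.42	0.38	decreased
4506085	Mitogen-activated protein kinase 13	MAPK13	0.0039	-0.27	0.54	decreased
4504073	Platelet glycoprotein Ib beta chain	GP1BB	0.0045	-0.26	0.55	decreased
12545406	ras GTPase-activating protein 1	RASA1	0.0053	-0.20	0.63	decreased
4757774	ADP-ribosylation factor-like protein 3	ARL3	0.0067	-0.24	0.58	decreased
410173533	PREDICTED: uncharacterized protein LOC100996504	ENSG000263264	0.0070	-0.27	0.54	decreased
29826335	Eukaryotic translation initiation factor 2 subunit 2	EIF2S2	0.0080	-0.25	0.56	decreased
30181236	copine-2	CPNE2	0.0087	-0.31	0.49	decreased
190014603	TBC1 domain family member 13	TBC1D13	0.0087	-0.26	0.55	decreased
4504077	Platelet glycoprotein IX	GP9	0.0089	-0.31	0.49	decreased
157738645	Plexin-A4	PLXNA4	0.0092	-0.38	0.42	decreased
4504351	Hemoglobin subunit delta	HBD	0.0093	-0.33	0.47	decreased
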