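protein_name	p_value	fold_change	direction
FUN14 domain-containing protein 2	0.00023	1.91	increased
NADH dehydrogenase [ubiquinone] 1 beta subcomplex subunit 3	0.00034	1.60	increased
d-beta-hydroxybutyrate dehydrogenase	0.00090	2.89	increased
Inositol-3-phosphate synthase 1	0.0025	1.82	increased
Mitochondrial 2-oxoglutarate/malate carrier protein	0.0042	1.78	increased
Phosphate carrier protein	0.0060	2.22	increased
ATP synthase subunit epsilon	0.0079	1.70	increased
Glyceraldehyde-3-phosphate dehydrogenase, testis-specific	0.0081	2.31	increased
Thioredoxin domain-containing protein 17	0.0065	1.58	increased
Prohibitin	0.0079	1.40	increased
Selenoprotein H	0.013	1.62	increased
Endophilin-B1	0.014	1.46	increased
Thioredoxin reductase 2	0.014	2.18	increased
Up-regulated during skeletal muscle growth protein 5	0.014	1.79	increased
Glutamine-dependent NAD(+) synthetase	0.014	1.53	increased
Poly [ADP-ribose] polymerase 4	0.015	1.65	increased
NADH dehydrogenase [ubiquinone] 1 alpha subcomplex subunit 3	0.015	1.58	increased
NADH dehydrogenase [ubiquinone] 1 beta subcomplex subunit 11	0.016	1.64	increased
ATP synthase subunit delta	0.017	1.78	increased
Poly [ADP-ribose] polymerase 14	0.018	1.78	increased
Single-stranded DNA-binding protein	0.019	1.51	increased
Ubiquinone biosynthesis protein COQ9	0.020	1.77	increased
NADH dehydrogenase [ubiquinone] 1 alpha subcomplex subunit 12	0.020	1.76	increased
Short-chain specific acyl-CoA dehydrogenase	0.020	1.49	increased
Glycerol-3-phosphate dehydrogenase	0.021	1.40	increased
2-oxoglutarate dehydrogenase	0.025	1.35	increased
Aconitate hydratase	0.025	1.36	increased
39S ribosomal protein L43	0.027	1.55	increased
Cytochrome c oxidase assembly factor 6 homolog	0.028	1.47	increased
Biogenesis of lysosome-related organelles complex 1 subunit 1	0.030	2.04	increased
Pyruvate dehydrogenase E1 component subunit beta	0.032	1.31	increased
BRI3-binding protein	0.033	2.27	increased
Trifunctional enzyme subunit beta	0.034	1.40	increased
ATP synthase subunit b	0.035	1.49	increased
Putative transferase CAF17	0.036	1.30	increased
Glycine--tRNA ligase	0.037	1.47	increased
39S ribosomal protein L12, mitochondrial	0.038	1.63	increased
Peptidyl-prolyl cis-trans isomerase NIMA-interacting 4 isoform 1	0.040	1.46	increased
Isocitrate dehydrogenase [NAD] subunit beta, mitochondrial isoform a precursor	0.042	2.17	increased
Mitochondrial fission 1 protein	0.047	1.48	increased
Isocitrate dehydrogenase [NADP], mitochondrial precursor	0.0001	0.59	decreased
Peptidyl-prolyl cis-trans isomerase F, mitochondrial precursor	0.0005	0.38	decreased
Peroxiredoxin-6	0.0081	0.66	decreased
Thiosulfate sulfurtransferase	0.0092	0.65	decreased
Choline transporter-like protein 1	0.011	0.36	decreased
39S ribosomal protein L23, mitochondrial	0.012	0.45	decreased
Mitochondrial import inner membrane translocase subunit Tim8 A isoform 1	0.012	0.47	decreased
Cytochrome c	0.013	0.56	decreased
ATP synthase mitochondrial F1 complex assembly factor 1 isoform 2 precursor	0.013	0.60	decreased
ATP-binding cassette sub-family B member 7, mitochondrial isoform 1	0.018	0.55	decreased
Dynamin-1-like protein isoform 1	0.019	0.68	decreased
Stimulator of interferon genes protein	0.036	0.61	decreased
Oxidation resistance protein 1 isoform 4	0.037	0.69	decreased
NADH dehydrogenase [ubiquinone] 1 alpha subcomplex subunit 5	0.040	0.60	decreased
Glycerol kinase isoform b	0.047	0.70	decreased
CCA tRNA nucleotidyltransferase 1, mitochondrial	0.048	0.57	decreased
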