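gene_id	gene_name	regulon_class	binding_site	rpkm_wt	rpkm_mut	fold_change	product
blr0149	cyoA	repressed	TGCGGCGCAGCA	22.29	77.7	3.49	cytochrome O ubiquinol oxidase subunit II
blr0899	phaZ3	repressed	TGCAGTGCAGCA	32.68	89.48	2.74	poly(3-hydroxyalkanoate) depolymerase
blr0908	phaZ1	repressed	CGCATCGCAGCA	129.32	542.25	4.19	poly(3-hydroxybutyrate) depolymerase
bll1447	rhlE	repressed	TGCAGTGCAGAA	152.94	551.69	3.61	dead-box ATP-dependent RNA helicase
blr2242	.	repressed	TGCGCCGCAGCA	66.21	190.65	2.88	unknown protein
bll2363	.	repressed	TGCGCCGCACAA	374.44	1256.32	3.36	unknown protein
blr2367	.	repressed	TGCACCGCAGCA	55.14	347.34	6.30	acetyltransferase
bll2471	.	repressed	TGGATCGCACCA	86.78	512.16	5.90	hypothetical protein (Hemerythrin HHE cation binding region)
bll2537	.	repressed	CGCGTCGCAGCA	39.54	83.05	2.10	hypothetical protein
blr2887	phaP5	repressed	TGCATCGCACAA	122.86	15882.63	129.27	phasin
blr2955	ppc	repressed	TGCGCTGCGGCA	46.27	93.71	2.03	PEP carboxylase
bll3794	.	repressed	TGCATTGCAGCG	104.59	404.72	3.87	hypothetical protein
blr4162	.	repressed	TGCATCGCACCA	79.46	931	11.72	hypothetical protein (cellulose synthase catalytic subunit protein)
bsr4236	.	repressed	TGCATTGCAACA	38.73	435.02	11.23	unknown protein
blr4486	nifR	repressed	TGCAGTGCAGCA	112.16	225.25	2.01	nitrogen regulation protein
blr4501	metN	repressed	TGCACCGCAACA	14.42	29.08	2.02	probable ABC transporter ATP-binding protein
bsr4726	.	repressed	TGCGGTGCACAC	157.38	1402.14	8.91	hypothetical protein
bll4785	.	repressed	CGCGCCGCACAA	90.88	279.72	3.08	transcriptional regulatory protein Fis family
bll5155	phaP1	repressed	TGCAACGCACAA	215.67	10738.12	49.79	phasin
bsr5273	.	repressed	TGCGGTGCATCA	45.13	222.49	4.93	hypothetical protein
bll5524	.	repressed	AGCAGTGCAGCA	106.54	220.06	2.07	hypothetical protein
blr5525	.	repressed	AGCAGTGCAGCA	23.4	46.85	2.00	hypothetical protein
blr5594	.	repressed	TGCGGCGCACAA	26.16	71.75	2.74	MFS permease
bll6290	.	repressed	TGCGGCGGACCA	146.99	458.11	3.12	two-component response regulator
blr6718	.	repressed	TGCCATGCAGCA	42.45	111.4	2.62	hypothetical protein
blr7089	nirK	repressed	TGCGCTGCAACA	13.49	41.36	3.07	respiratory nitrite reductase
bll7395	phaP4	repressed	TGCGCTGCACAA	489.78	2956.78	6.04	phasin
blr7872	.	repressed	TGCGCTGCAACA	6.30	20.63	3.27	HlyD family secretion protein
bll0225	phbB2	activated	TGCGCTGCACAC	154.34	74.52	2.07	acetoacetyl CoA reductase
bll0304	ragA	activated	TGCGACGCCGCA	8.95	2.29	3.91	two-component response regulator
blr0305	.	activated	TGCGACGCCGCA	45.61	16.48	2.77	unknown protein
bll0805	.	activated	CGCAACGCACAA	185.17	76.29	2.43	hypothetical protein
blr0806	.	activated	CGCAACGCACAA	52.09	23.58	2.21	hypothetical protein
bll1416	.	activated	TGCGCGGCAGCA	52.49	20.56	2.55	unknown protein
blr2204	.	activated	TGCAGTCCAGAA	19.07	9.05	2.11	transcriptional regulatory protein AraC family
bll2446	.	activated	TTCGCCGCAGAA	275.72	129.25	2.13	hypothetical protein
bsr2601	.	activated	TGCACCGCAGCC	32.44	15.65	2.07	unknown protein
blr2810	.	activated	TGCATTGCGCAA	15.88	7.35	2.16	aldo/keto reductase
bll2914	.	activated	TGCGCTGGAGAA	25.07	9.61	2.61	probable amidase
bll3387	.	activated	TGCGCCGCAACA	278.27	54.25	5.13	unknown protein
blr3795	.	activated	TGCATTGCAGCG	40.09	19.03	2.11	ABC transporter HlyB/MsbA family
blr3904	.	activated	TGCAGTGCTGCA	312.33	109.92	2.84	probable iron transport protein
blr4188	.	activated	CGCAGTGCAGCA	28.85	12.98	2.22	hypothetical protein
bll4430	.	activated	TGCAGCGCAGCA	104.34	38.21	2.73	hypothetical protein
bsr4431	.	activated	TGCAGCGCAGCA	216.36	77.85	2.78	hypothetical protein
bll4783	pdhA	activated	TGCAGTGCGGCA	249.67	111.10	2.25	pyruvate dehydrogenase alpha subunit
bll4833	.	activated	TGCGGCGCACCA	530.73	140.09	3.79	unknown protein
bsr4834	.	activated	TGCGGCGCACCA	168.95	52.96	3.19	unknown protein
blr4841	.	activated	TGCCGCGCACAA	30.64	14.59	2.10	unknown protein
bll4952	.	activated	TGCATCGCACAA	27.07	7.50	3.61	NfeD protein homolog
bll5160	.	activated	TGCGGCGCACAA	106.54	46.40	2.30	conserved hypothetical protein; putative alpha/beta-Hydrolases
bsl5321	.	activated	CGCGGCGCAGCA	415.34	205.51	2.02	unknown protein
bll5335	.	activated	TGCGCCGGACAA	35.29	16.85	2.09	putative thiolase
blr5540	.	activated	TGCGGTGCCCAA	231.26	58.07	3.98	hypothetical protein
bsl5717	.	activated	TGCGGCGCCCAA	109.78	34.94	3.14	hypothetical protein
bll5961	.	activated	TGCGGTGCAACA	12.66	4.23	2.99	transcriptional regulatory protein Crp family
blr5962	.	activated	TGCGGTGCAACA	40.98	7.40	5.54	ABC transporter ATP-binding protein
bll6121	.	activated	TGCAGCGCACAA	21.88	9.39	2.33	probable sulfite oxidase
bll6206	.	activated	CGCGCCGCACAA	74.19	35.28	2.10	hypothetical protein
blr6207	exaA	activated	CGCGCCGCACAA	93.32	23.85	3.91	probable quinoprotein ethanol dehydrogenase precursor
blr6443	.	activated	TGCAATGCAACA	13.79	2.83	4.87	ABC transporter permease protein
blr6465	.	activated	CGCGATGCACAA	39.03	14.29	2.73	putative steroid monooxygenase
bll6733	.	activated	TGCGACGAAGCA	45.09	21.88	2.06	putative amidase
bsr6735	pqqA	activated	TGCAGTGCAACA	156.84	40.03	3.92	putative pyrroloquinoline quinone synthesis protein A
blr6837	.	activated	CGCAGTGCAGCA	34.10	7.30	4.67	hypothetical protein
blr6886	.	activated	CGCATTGCACAA	57.55	25.47	2.26	transcriptional regulatory protein MarR family
bll7487	.	activated	TGCGGAGCACAA	456.33	176.20	2.59	unknown protein
bll7511	.	activated	TGCAACGCAGAT	167.13	62.44	2.68	unknown protein
bll7663	.	activated	TGCACCGCAGCA	57.90	24.14	2.40	unknown protein
bll8141	pckA	activated	TGCGACGCACAA	386.03	107.43	3.59	phosphoenolpyruvate carboxykinase
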