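category	sub_pathway	gene_id	description	fc_1w	fc_4w
cell_proliferation		AIF1	Allograft inflammatory factor 1 isoform 1	2.81	4.23
cell_proliferation		ANGPT1	Angiopoietin-1 precursor	3.21	2.18
cell_proliferation		APOA1	Apolipoprotein A-I	2.12	4.42
cell_proliferation		BLOC1S2	Biogenesis of lysosome-related organelles complex-1 subunit 2	3.35	2.98
cell_proliferation		CDK14	Cyclin-dependent kinase 14 isoform 3	4.91	1.45
cell_proliferation		CLEC11A	C-type lectin domain family 11 member A	4.33	5.44
cell_proliferation		CXCL12	Stromal cell-derived factor 1 precursor	2.52	4.36
cell_proliferation		DLC1	Rho GTPase-activating protein 7	4.75	2.67
cell_proliferation		DPT	Dermatopontin	3.84	2.01
cell_proliferation		FGF18	Fibroblast growth factor 18	2.37	2.81
cell_proliferation		FYN	Tyrosine-protein kinase Fyn isoform 2	2.05	2.62
cell_proliferation		HES4	Transcription factor HES-4	2.16	2.18
cell_proliferation		LECT1	Leukocyte cell-derived chemotaxin 1	3.68	9.13
cell_proliferation		MAP2K1	Dual specificity mitogen-activated protein kinase 1	2.42	3.64
cell_proliferation		MSX1	Homeobox protein MSX-1	3.49	2.94
cell_proliferation		NFIB	Nuclear factor 1 B-type isoform 3	2.73	2.94
cell_proliferation		PDGFRA	Platelet-derived growth factor receptor alpha	3.94	2.42
cell_proliferation		PLCD1	1-Phosphatidylinositol-4,5-bisphosphate phosphodiesterase delta-1 isoform 3	4.40	3.63
cell_proliferation		RBP4	Retinol-binding protein 4	4.08	6.30
cell_proliferation		SERPINF1	Pigment epithelium-derived factor	4.82	3.27
cell_proliferation		SMYD2	N-lysine methyltransferase SMYD2	2.29	2.76
cell_proliferation		TBX2	T-box transcription factor TBX2	2.22	5.48
cell_proliferation		VEGFC	Vascular endothelial growth factor C	3.00	2.82
cell_proliferation		VSIG4	V-set and immunoglobulin domain-containing protein 4	4.73	4.18
cell_proliferation		ZBTB16	Zinc finger and BTB domain-containing protein 16 isoform 2	3.25	5.25
ecm		BGN	Biglycan precursor	12.26	5.86
ecm		COL1A2	Collagen alpha-2(I) chain precursor	9.27	1.28
ecm		COL5A3	Collagen alpha-3(V) chain	6.95	7.00
ecm		DCN	Decorin precursor	6.23	4.29
ecm		DPT	Dermatopontin	3.84	2.01
ecm		EFEMP1	EGF containing fibulin-like extracellular matrix protein 1	3.33	2.58
ecm		FBLN1	Fibulin-1	3.14	1.53
ecm		FBLN5	Fibulin-5	5.21	4.02
ecm		FBN1	Fibrillin-1 isoform 3	6.67	-2.52
ecm		FMOD	Fibromodulin	3.18	3.05
ecm		FN1	Fibronectin	3.59	-1.19
ecm		LAMB2	Laminin subunit beta-2	1.21	2.21
ecm		LUM	Lumican	6.28	2.55
ecm		MMP11	Stromelysin-3 precursor	1.51	2.06
ecm		NID1	Nidogen-1 isoform 1	4.87	3.02
ecm		OGN	Mimecan	12.21	3.05
ecm		PCOLCE	Procollagen C-endopeptidase enhancer 1 isoform 3	3.17	2.00
ecm		PDGFRA	Platelet-derived growth factor receptor alpha	3.94	2.42
ecm		POSTN	Periostin	5.61	2.39
ecm		PRELP	Prolargin	7.41	6.22
ecm		SERPINF1	Pigment epithelium-derived factor	4.82	3.27
ecm		SMOC2	SPARC related modular calcium binding 2 precursor	7.68	11.27
ecm		TIMP3	Metalloproteinase inhibitor 3 isoform 1	4.19	2.08
ecm		TNC	Tenascin precursor	6.19	6.87
ecm		VTN	Vitronectin isoform 2	1.06	4.33
growth_factors		ANGPT4	Angiopoietin-4	4.65	9.81
growth_factors		CLEC11A	C-type lectin domain family 11 member A	4.33	5.44
growth_factors		CLEC3B	Tetranectin	3.31	6.98
growth_factors		CRIM1	Cysteine-rich motor neuron 1 protein	4.27	3.51
growth_factors		EFEMP1	EGF containing fibulin-like extracellular matrix protein 1	3.33	2.58
growth_factors		ESM1	Endothelial cell-specific molecule 1 isoform 2	3.37	7.04
growth_factors		FGF13	Fibroblast growth factor 13 isoform 1	1.67	2.33
growth_factors		FGF18	Fibroblast growth factor 18	2.37	2.81
growth_factors		FGF23	Fibroblast growth factor 23	-1.12	3.93
growth_factors		FYN	Tyrosine-protein kinase Fyn isoform 2	2.05	2.62
growth_factors		IGFBP2	Insulin-like growth factor binding protein 2	2.89	-1.44
growth_factors		IGFBP6	Insulin-like growth factor binding protein 6 isoform 3	3.11	2.45
growth_factors		LECT1	Leukocyte cell-derived chemotaxin 1	3.68	9.13
growth_factors		LRP1	Prolow-density lipoprotein receptor-related protein 1	2.25	3.28
growth_factors		LTBP3	Latent-transforming growth factor beta-binding protein 3	1.76	2.79
growth_factors		NRP2	Neuropilin-2 isoform 4	8.79	3.50
growth_factors		PDGFRA	Platelet-derived growth factor receptor alpha	3.94	2.42
growth_factors		PTN	Pleiotrophin	3.28	2.34
growth_factors		SIRT1	NAD-dependent deacetylase sirtuin-1 isoform 1	2.67	2.93
growth_factors		SMAD6	Mothers against decapentaplegic homolog 6	2.36	6.82
growth_factors		TGFB1	Transforming growth factor beta-1 precursor	4.07	8.44
growth_factors		TWF2	Twinfilin-2	2.49	2.92
growth_factors		VEGFC	Vascular endothelial growth factor C	3.00	2.82
growth_factors		WISP2	WNT1-inducible-signaling pathway protein 2	8.61	6.15
growth_factors		YWHAG	14-3-3 protein gamma	3.26	2.45
osteogenesis	core	CYR61	Protein CYR61	3.03	1.67
osteogenesis	core	DLX5	Homeobox protein DLX-5 isoform 2	3.03	9.05
osteogenesis	core	FGF23	Fibroblast growth factor 23	-1.12	3.93
osteogenesis	core	ID3	DNA-binding protein inhibitor ID-3	2.55	3.22
osteogenesis	core	ILK	Integrin-linked protein kinase isoform 1	2.49	1.38
osteogenesis	core	OSR2	Protein odd-skipped-related 2 isoform 1	4.71	1.74
osteogenesis	core	PTH1R	Parathyroid hormone/parathyroid hormone-related peptide receptor precursor	1.95	20.12
osteogenesis	core	SFRP2	Secreted frizzled-related protein 2 precursor	3.34	4.35
osteogenesis	core	SMAD3	Mothers against decapentaplegic homolog 3	2.10	-1.15
osteogenesis	core	SMOC1	SPARC-related modular calcium-binding protein 1 isoform 1	3.83	4.36
osteogenesis	core	SNAI1	Zinc finger protein SNAI1	2.26	2.66
osteogenesis	core	SNAI2	Zinc finger protein SNAI2	2.81	2.61
osteogenesis	core	TYROBP	TYRO protein tyrosine kinase-binding protein precursor	1.44	2.12
osteogenesis	tgf_beta_bmp	BMP5	Bone morphogenetic protein 5 isoform 1	2.68	2.34
osteogenesis	tgf_beta_bmp	BMPER	BMP-binding endothelial regulator protein	1.77	3.14
osteogenesis	tgf_beta_bmp	CYR61	Protein CYR61	3.03	1.67
osteogenesis	tgf_beta_bmp	DLX5	Homeobox protein DLX-5 isoform 2	3.03	9.05
osteogenesis	tgf_beta_bmp	GATA3	Trans-acting T-cell-specific transcription factor GATA-3 isoform 1	2.19	1.01
osteogenesis	tgf_beta_bmp	HES4	Transcription factor HES-4	2.16	2.18
osteogenesis	tgf_beta_bmp	MSX1	Homeobox protein MSX-1	3.49	2.94
osteogenesis	tgf_beta_bmp	SFRP2	Secreted frizzled-related protein 2 precursor	3.34	4.35
osteogenesis	tgf_beta_bmp	SMAD6	Mothers against decapentaplegic homolog 6	2.36	6.82
osteogenesis	tgf_beta_bmp	TGFB1	Transforming growth factor beta-1 precursor	4.07	8.44
osteogenesis	wnt	BARX1	BARX homeobox 1	-1.03	25.85
osteogenesis	wnt	CDK14	Cyclin-dependent kinase 14 isoform 3	4.91	1.45
osteogenesis	wnt	DKK1	Dickkopf-related protein 1	12.93	2.09
osteogenesis	wnt	DLX5	Homeobox protein DLX-5 isoform 2	3.03	9.05
osteogenesis	wnt	FZD1	Frizzled-1	4.08	2.10
osteogenesis	wnt	FZD2	Frizzled-2	2.05	1.30
osteogenesis	wnt	HIC1	Hypermethylated in cancer 1 protein isoform 1	2.62	2.03
osteogenesis	wnt	LATS2	Serine/threonine-protein kinase LATS2	4.14	2.15
osteogenesis	wnt	LRP1	Prolow-density lipoprotein receptor-related protein 1	2.25	3.28
osteogenesis	wnt	LRP5	Low-density lipoprotein receptor-related protein 5	2.89	1.43
osteogenesis	wnt	NXN	Nucleoredoxin	3.35	2.48
osteogenesis	wnt	SFRP2	Secreted frizzled-related protein 2 precursor	3.34	4.35
osteogenesis	wnt	SFRP4	Secreted frizzled-related protein 4 isoform 1	2.90	4.82
osteogenesis	wnt	SNAI2	Zinc finger protein SNAI2	2.81	2.61
osteogenesis	wnt	WISP2	WNT1-inducible-signaling pathway protein 2	8.61	6.15
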