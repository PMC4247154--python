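category	gene	pct_reversion	identity_bm	identity_tc	identity_dm	forced_include
Core RNAi factors	Argonaute-1	48.69	48	88	3	False
Core RNAi factors	Argonaute-3	12.25	69	44	43	False
Core RNAi factors	Dicer-2	43.61	64	38	30	False
Core RNAi factors	Dicer-1	25.43	68	43	40	False
Core RNAi factors	Aubergine	41.42	69	49	44	False
Core RNAi factors	Drosha	39.97	84	66	60	False
Core RNAi factors	Pasha	45.56	69	53	38	False
Core RNAi factors	Loquacious	16.56	84	66	56	False
Core RNAi factors	R2D2	23.74	60	28	30	False
DEAD RNA helicase domain proteins	Dbp45A subfamily	24.22	87	56	57	False
DEAD RNA helicase domain proteins	VASA subfamily	31.08	80	59	58	False
DEAD RNA helicase domain proteins	DDX18/HAS1 subfamily	61.54	74	53	52	False
RNA processing module	U1A snRNP	36.87	90	83	73	False
RNA processing module	SmG	23.79	94	83	77	False
RNA processing module	Integrator complex subunit (Int11)	76.11	99	92	91	False
RNA processing module	Zn finger protein	38.76	93	53	3	False
RNA processing module	Regulator of nonsense transcripts 1 homolog (smg-2 like)	11.45	97	81	76	False
Protein Kinase family of signalling allied components	CaM Kinase	25.86	96	84	83	False
Protein Kinase family of signalling allied components	Serine/threonine p21-activated kinase (PAK) mbt like protein	31.32	86	62	79	False
Protein Kinase family of signalling allied components	cAMP-dependent protein kinase C1	39.39	99	89	5	False
Protein Kinase family of signalling allied components	Protein Kinase C	21.58	97	92	87	False
Protein Kinase family of signalling allied components	IKK-beta	30.39	66	36	30	False
Protein Kinase family of signalling allied components	STE20/Fray	40.41	86	75	73	False
Protein Kinase family of signalling allied components	MAPKK4	39.96	90	75	73	False
Multi drug resistance cassette transporter	MDR1A	67.51	73	51	46	False
Tudor domain protein	Tudor		79	56	54	True
Sid like protein	Sil-2	9.23	65	33		False
Chromatin factors	Histone3 Lysine4 N-methyltransferase	38.57	82	45	60	False
Chromatin factors	Histone deacetylase 3 like	26.71	94	85	79	False
Chromatin factors	Gas41	26.92	88	71	70	False
Translational unit	eIF2B-gamma	30.55	79	48	41	False
Translational unit	eIF4AII	24.16	96	83	80	False
Translational unit	eIF4AIII	30.92	99	93	96	False
Translational unit	RPL23P	28.09	98	93	84	False
Cell division associated elements	KIF18A-like	24.97	76	63	59	False
Cell division associated elements	Cyclin-dependent kinase 5 homolog	23.61	99	91	80	False
Cell division associated elements	KIF3A-like	44.75	96	58	69	False
Metabolic factor	Isocitrate dehydrogenase [NAD] subunit alpha	67.32	82	79	72	False
Others	Myosin VIIa-like	26.44	95	88	84	False
Others	Nucleolar complex protein 2 homolog	35.81	69	53	55	False
Others	WD 40 like repeat domain	30.55	97	94	90	False
Others	S-phase kinase-associated protein (SkpA)	35.79	89	38	3	False
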