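lake	category	core_asv_count	components	edges	pct_positive_edges	pct_negative_edges	clustering_coefficient	modularity	pct_lcc_nodes	pct_connected_phototroph	pct_connected_mixotroph	pct_connected_phagotroph	pct_connected_parasite	pct_modules_all_four_modes	module_mean_trophic_richness
VSM	oligo_meso	128	82	85	62.35	37.65	0.46	0.50	30.47	42.31	13.46	32.69	11.54	0.00	2.18
JAB	oligo_meso	126	98	38	71.05	28.95	0.55	0.57	14.29	34.21	15.79	36.84	13.16	0.00	1.57
CER-L	oligo_meso	137	82	139	70.50	29.50	0.52	0.39	35.77	32.26	17.74	45.16	4.84	8.33	2.17
CER-S	meso_eu	132	99	64	73.44	26.56	0.62	0.49	21.21	42.11	23.68	23.68	10.53	11.11	2.33
CRE	meso_eu	126	89	50	96.00	4.00	0.75	0.88	5.56	54.72	13.21	22.64	9.43	0.00	1.71
BLR	meso_eu	151	87	125	60.80	39.20	0.41	0.45	42.38	36.36	22.73	36.36	4.55	22.22	2.56
LGP	meso_eu	167	126	48	85.42	14.58	0.44	0.81	11.38	31.37	19.61	39.22	9.80	0.00	1.64
CSM	eu_hyper	154	112	91	98.90	1.10	0.79	0.74	7.14	37.04	22.22	27.78	12.96	0.00	2.33
VSS	eu_hyper	188	142	67	97.01	2.99	0.64	0.86	5.32	31.67	20.00	38.33	10.00	0.00	1.73
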