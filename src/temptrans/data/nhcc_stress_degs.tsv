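gene_id	T25	T4	T0	TM4	T44	regulation	annotation
CL4489.Contig2	0.02	24.17	22.42	26.90	11.41	Up	Unknown protein
CL10212.Contig2	0.00	6.52	4.30	7.03	4.30	Up	Glycosyl transferase family 1 protein
CL3727.Contig8	153.31	6.14	26.06	2.08	2.71	Down	Hypothetical protein ARALYDRAFT_910104
CL11270.Contig1	0.78	21.25	81.51	13.92	43.86	Up	Late embryogenesis abundant protein LEA14
Unigene519	0.12	209.31	1750.16	67.05	157.31	Up	BN28b, stress-induced protein KIN2 mRNA
CL8814.Contig1	139.12	12.75	2.07	1.84	3.27	Down	BN28a gene
Unigene16735	0.00	5.36	2.14	8.70	3.29	Up	Unknown protein
CL536.Contig12	0.00	3.12	7.09	10.66	8.15	Up	Wound-induced protein 1
Unigene50726	11.94	0.00	0.00	0.12	0.00	Down	ATP synthase CF1 epsilon chain, chloroplast
CL2980.Contig1	8.18	203.56	272.71	191.73	317.44	Up	BN28a, stress-induced protein KIN2
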