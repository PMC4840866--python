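gene_id	pfam_id	tf_family	pfam_evalue	log2fc_T4	q_T4	log2fc_T0	q_T0	log2fc_TM4	q_TM4
CL10543.Contig2	PF00067.17	p450	8.90E-32	6.74	0.8445	6.32	0.8308	6.34	0.838
CL11270.Contig2	PF03168.8	LEA_2	2.10E-18	5.78	0.836	6.05	0.8397	3.24	0.8154
CL11755.Contig1	PF00295.12	Glyco_hydro_28	2.60E-09	-11.3	0.8584	-11.3	0.8635	-11.3	0.8281
CL13372.Contig2	PF00657.17	Lipase_GDSL	5.20E-28	-3.71	0.8189	-3.64	0.818	-2.64	0.806
CL3153.Contig1	PF00201.13	UDPGT	3.90E-26	3.32	0.82	3.33	0.8193	2.79	0.8159
CL6375.Contig2	PF00067.17	p450	1.90E-22	-3.79	0.8254	-2.98	0.8155	-4.06	0.8365
Unigene12001	PF00764.14	Arginosuc_synth	6.50E-52	-11.6	0.8841	-11.6	0.8882	-11.6	0.8574
Unigene16263	PF00206.15	Lyase_1	1.40E-29	-11.32	0.8599	-11.32	0.865	-11.32	0.8298
Unigene20049	PF00314.12	Thaumatin	1.50E-16	-4.95	0.8083	-3.92	0.8048	-3.35	0.8017
Unigene20728	PF01676.13	Metalloenzyme	6.40E-21	-11.15	0.8443	-11.15	0.8502	-11.15	0.8126
Unigene22237	PF00504.16	Chloroa_b-bind	2.00E-48	2.49	0.8025	3.69	0.8241	3.23	0.8285
Unigene2424	PF00067.17	p450	6.80E-07	6.18	0.806	6.67	0.8301	7.13	0.8527
Unigene2446	PF00206.15	Lyase_1	3.00E-26	-11.94	0.9086	-11.94	0.9119	-11.94	0.8861
Unigene24606	PF02800.15	Gp_dh_C	4.60E-51	-12.68	0.9492	-12.68	0.9515	-12.68	0.9354
Unigene26264	PF02775.16	TPP_enzyme_C	1.10E-10	-11.31	0.8594	-11.31	0.8645	-11.31	0.8292
Unigene42146	PF00006.20	ATP-synt_ab	2.30E-33	-11.43	0.8698	-11.43	0.8745	-11.43	0.841
Unigene50595	PF00764.14	Arginosuc_synth	2.60E-26	-11.15	0.8443	-11.15	0.8502	-11.15	0.8126
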