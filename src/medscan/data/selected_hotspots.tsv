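hotspot	chrom	cm_start	cm_end	trait_classes	left_marker	left_bp	right_marker	right_bp	ci_mb	n_gene_models
1A.1	1A	21	27	C,E,P	BS00023201_51	7643102	Excalibur_c71158_54	8296998	0.65	19
1A.2	1A	51	53	P	Excalibur_c10689_254	27363007	Kukri_c22508_119	28757949	1.39	9
1A.4	1A	95	96	C	BS00062876_51	529788778	BobWhite_c96_170	531682571	1.89	34
1B.1	1B	43	45	C	BS00065053_51	38833829	wsnp_Ex_c5780_10153638	26186242	12.65	89
1B.2	1B	51	53	P	Excalibur_c95656_129	44933589	Tdurum_contig56188_569	28563880	16.37	114
1B.3	1B	62	64	C	wsnp_BE399980B_Ta_2_1	142523393	BS00003575_51	148898343	6.37	27
1B.5	1B	86	91	C,E,P	Kukri_c25961_166	575863858	BobWhite_c39656_106	589919646	14.06	147
1B.6	1B	111	116	C	BS00094237_51	638015155	BS00084895_51	643101677	5.09	78
1B.7	1B	134	136	P	GENE-0063_68	661515587	Excalibur_rep_c71107_517	664599715	3.08	35
1B.8	1B	159	161	P	GENE-0543_201	681690469	Excalibur_rep_c69522_83	685865389	4.17	41
1B.9	1B	172	174	P	wsnp_Ex_c1597_3045682	688283056	wsnp_Ku_c13952_22097856	687413792	0.87	9
1D.1	1D	161	172	C	RAC875_c14613_68	485557589	RFL_Contig3395_1575	487168787	1.61	34
1D.2	1D	179	180	C	BS00093275_51	486241852	Tdurum_contig29915_167	491043383	4.80	75
2A.1	2A	74	75	P	Tdurum_contig11803_306	36041083	Ku_c269_2643	36632073	0.59	15
2A.2	2A	122	123	C	BS00107804_51	707040172	wsnp_Ex_rep_c66358_64543401	709701422	2.66	30
2A.3	2A	143	144	C	BS00062732_51	747090405	Excalibur_c18514_238	750595232	3.50	90
2B.3	2B	147	148	C	BobWhite_c12911_788	780590397	BS00100118_51	788524935	7.93	108
2D.1	2D	8	9	P	BS00067698_51	14860348	BS00047901_51	15967448	1.11	30
3B.1	3B	37	38	C	Tdurum_contig43252_1762	23782080	TA001028-0737	24007966	0.23	8
3B.3	3B	67	69	C,P	Ku_c27771_508	495471559	BS00030430_51	503989868	8.52	52
4B.1	4B	55	57	C	Ra_c26080_461	36642697	BS00095416_51	40233919	3.59	30
5A.2	5A	84	86	C	BS00073670_51	570716220	Excalibur_c472_914	568272220	2.44	40
5A.3	5A	90	92	P	Kukri_c10033_724	584677742	Excalibur_c26671_57	591319197	6.64	87
5A.4	5A	115	116	C	BS00076948_51	664273096	Tdurum_contig11521_102	665779594	1.51	20
5B.2	5B	60	61	C	RAC875_c38511_91	476805518	RAC875_c2437_1569	479025121	2.22	39
6B.1	6B	39	40	C	RAC875_c2291_123	41705928	RAC875_c13920_836	42778537	1.07	23
6B.2	6B	73	74	E	BobWhite_c28409_462	635175311	wsnp_Ex_c1276_2445537	642348416	7.17	39
6B.3	6B	84	86	P	Kukri_c58961_76	669019620	Tdurum_contig68217_361	674946651	5.93	50
6B.4	6B	120	121	P	Kukri_c60966_261	719509426	Tdurum_contig10729_989	720983865	1.47	25
7A.3	7A	207	211	E	BobWhite_c32347_219	708145137	Ku_c19745_1093	712058458	3.91	74
7A.4	7A	215	218	E	BS00027226_51	717965474	Kukri_c9728_1171	719567332	1.60	14
7A.5	7A	227	229	C,E	BS00020236_51	730426125	Tdurum_contig46717_2021	731267973	0.84	18
7B.1	7B	57	59	C,P	GENE-4826_641	61557711	BS00091302_51	64726430	3.17	31
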