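hotspot	marker	cm	bp	subpop	allele	frequency
2B.1	Kukri_c35153_956	102.2	539965301	SP1	A	0.54
2B.1	Kukri_c35153_956	102.2	539965301	SP1	G	0.46
2B.1	Kukri_c35153_956	102.2	539965301	SP2	A	0.25
2B.1	Kukri_c35153_956	102.2	539965301	SP2	G	0.75
2B.1	Kukri_c35153_956	102.2	539965301	SP3	A	0.91
2B.1	Kukri_c35153_956	102.2	539965301	SP3	G	0.09
2B.1	Kukri_c35153_145	104.4	539964058	SP1	A	0.46
2B.1	Kukri_c35153_145	104.4	539964058	SP1	G	0.54
2B.1	Kukri_c35153_145	104.4	539964058	SP2	A	0.75
2B.1	Kukri_c35153_145	104.4	539964058	SP2	G	0.25
2B.1	Kukri_c35153_145	104.4	539964058	SP3	A	0.09
2B.1	Kukri_c35153_145	104.4	539964058	SP3	G	0.91
5B.1	wsnp_BE443187B_Ta_2_1	51.2	410531891	SP1	A	0.04
5B.1	wsnp_BE443187B_Ta_2_1	51.2	410531891	SP1	C	0.96
5B.1	wsnp_BE443187B_Ta_2_1	51.2	410531891	SP2	A	0.25
5B.1	wsnp_BE443187B_Ta_2_1	51.2	410531891	SP2	C	0.75
5B.1	wsnp_BE443187B_Ta_2_1	51.2	410531891	SP3	A	0.77
5B.1	wsnp_BE443187B_Ta_2_1	51.2	410531891	SP3	C	0.23
5B.3	RAC875_c19099_434	68.9	519153286	SP1	T	0.92
5B.3	RAC875_c19099_434	68.9	519153286	SP1	C	0.08
5B.3	RAC875_c19099_434	68.9	519153286	SP2	T	0.67
5B.3	RAC875_c19099_434	68.9	519153286	SP2	C	0.29
5B.3	RAC875_c19099_434	68.9	519153286	SP3	T	0.18
5B.3	RAC875_c19099_434	68.9	519153286	SP3	C	0.82
5B.3	Ra_c73292_443	69.2	513607799	SP1	A	0.08
5B.3	Ra_c73292_443	69.2	513607799	SP1	G	0.92
5B.3	Ra_c73292_443	69.2	513607799	SP2	A	0.46
5B.3	Ra_c73292_443	69.2	513607799	SP2	G	0.46
5B.3	Ra_c73292_443	69.2	513607799	SP3	A	0.55
5B.3	Ra_c73292_443	69.2	513607799	SP3	G	0.45
6B.2	GENE-1074_108	73.4	633906287	SP1	T	0.92
6B.2	GENE-1074_108	73.4	633906287	SP1	C	0.08
6B.2	GENE-1074_108	73.4	633906287	SP2	T	0.04
6B.2	GENE-1074_108	73.4	633906287	SP2	C	0.96
6B.2	GENE-1074_108	73.4	633906287	SP3	T	0.32
6B.2	GENE-1074_108	73.4	633906287	SP3	C	0.68
6B.2	GENE-4086_659	73.4	NA	SP1	A	0.04
6B.2	GENE-4086_659	73.4	NA	SP1	C	0.96
6B.2	GENE-4086_659	73.4	NA	SP2	A	0.50
6B.2	GENE-4086_659	73.4	NA	SP2	C	0.50
6B.2	GENE-4086_659	73.4	NA	SP3	A	0.36
6B.2	GENE-4086_659	73.4	NA	SP3	C	0.64
6B.2	GENE-4086_876	73.4	641286640	SP1	A	0.04
6B.2	GENE-4086_876	73.4	641286640	SP1	G	0.96
6B.2	GENE-4086_876	73.4	641286640	SP2	A	0.46
6B.2	GENE-4086_876	73.4	641286640	SP2	G	0.50
6B.2	GENE-4086_876	73.4	641286640	SP3	A	0.36
6B.2	GENE-4086_876	73.4	641286640	SP3	G	0.64
6B.2	Kukri_c59960_211	73.4	641291882	SP1	T	0.04
6B.2	Kukri_c59960_211	73.4	641291882	SP1	C	0.96
6B.2	Kukri_c59960_211	73.4	641291882	SP2	T	0.46
6B.2	Kukri_c59960_211	73.4	641291882	SP2	C	0.50
6B.2	Kukri_c59960_211	73.4	641291882	SP3	T	0.36
6B.2	Kukri_c59960_211	73.4	641291882	SP3	C	0.64
7A.4	Excalibur_c46453_144	217.0	719568282	SP1	A	0.19
7A.4	Excalibur_c46453_144	217.0	719568282	SP1	G	0.81
7A.4	Excalibur_c46453_144	217.0	719568282	SP2	A	0.50
7A.4	Excalibur_c46453_144	217.0	719568282	SP2	G	0.46
7A.4	Excalibur_c46453_144	217.0	719568282	SP3	A	0.59
7A.4	Excalibur_c46453_144	217.0	719568282	SP3	G	0.41
7A.4	Kukri_c9728_1171	217.0	719567232	SP1	A	0.81
7A.4	Kukri_c9728_1171	217.0	719567232	SP1	G	0.19
7A.4	Kukri_c9728_1171	217.0	719567232	SP2	A	0.46
7A.4	Kukri_c9728_1171	217.0	719567232	SP2	G	0.50
7A.4	Kukri_c9728_1171	217.0	719567232	SP3	A	0.41
7A.4	Kukri_c9728_1171	217.0	719567232	SP3	G	0.59
7B.2	wsnp_Ex_c106_217340	76.0	538868953	SP1	A	0.96
7B.2	wsnp_Ex_c106_217340	76.0	538868953	SP1	G	0.04
7B.2	wsnp_Ex_c106_217340	76.0	538868953	SP2	A	0.58
7B.2	wsnp_Ex_c106_217340	76.0	538868953	SP2	G	0.33
7B.2	wsnp_Ex_c106_217340	76.0	538868953	SP3	A	1.00
7B.2	wsnp_Ex_c106_217340	76.0	538868953	SP3	G	0.00
7B.2	Kukri_c51296_438	77.1	565911626	SP1	A	0.15
7B.2	Kukri_c51296_438	77.1	565911626	SP1	G	0.85
7B.2	Kukri_c51296_438	77.1	565911626	SP2	A	0.96
7B.2	Kukri_c51296_438	77.1	565911626	SP2	G	0.04
7B.2	Kukri_c51296_438	77.1	565911626	SP3	A	0.91
7B.2	Kukri_c51296_438	77.1	565911626	SP3	G	0.09
7B.2	wsnp_Ex_c5270_9324025	77.1	NA	SP1	T	0.15
7B.2	wsnp_Ex_c5270_9324025	77.1	NA	SP1	C	0.85
7B.2	wsnp_Ex_c5270_9324025	77.1	NA	SP2	T	0.96
7B.2	wsnp_Ex_c5270_9324025	77.1	NA	SP2	C	0.04
7B.2	wsnp_Ex_c5270_9324025	77.1	NA	SP3	T	0.91
7B.2	wsnp_Ex_c5270_9324025	77.1	NA	SP3	C	0.09
7B.2	wsnp_RFL_Contig4753_5709032	77.1	566481254	SP1	A	0.85
7B.2	wsnp_RFL_Contig4753_5709032	77.1	566481254	SP1	G	0.15
7B.2	wsnp_RFL_Contig4753_5709032	77.1	566481254	SP2	A	0.04
7B.2	wsnp_RFL_Contig4753_5709032	77.1	566481254	SP2	G	0.96
7B.2	wsnp_RFL_Contig4753_5709032	77.1	566481254	SP3	A	0.09
7B.2	wsnp_RFL_Contig4753_5709032	77.1	566481254	SP3	G	0.91
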