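block_id	start_bp	end_bp	block_distance_bp	haplotype	freq_total	freq_slick	freq_nonslick	p_value
2	35029690	35073431	43741	AGACGACG	0.126	0.292	0.025	8.39E-08
52	36293763	36306435	12672	AAGAAAG	0.111	0.264	0.017	1.39E-07
53	36311419	36313371	1952	CC	0.191	0.389	0.071	6.15E-08
58	36396764	36441238	44474	GCAAAGGGAGGGGGGGGCGGGGCAA	0.105	0.264	0.008	2.62E-08
87	37534901	37572302	37401	GCAAGGAGCAAAG	0.131	0.29	0.034	3.66E-07
94	37718791	37721846	3055	GGG	0.511	0.833	0.314	3.58E-12
94	37718791	37721846	3055	AAA	0.453	0.153	0.636	8.80E-11
100	37834790	37847125	12335	GGGCGA	0.184	0.389	0.059	1.31E-08
102	37885136	37935057	49921	GCAGAGGCGGAGAAGG	0.116	0.292	0.008	3.25E-09
104	37940179	37957238	17059	GGGGA	0.111	0.292	0	4.96E-10
110	38182103	38220127	38024	GCAAGG	0.119	0.289	0.015	1.59E-08
112	38224054	38281493	57439	GGGGAGG	0.105	0.278	0	1.44E-09
117	38384676	38412185	27509	AAGAGGAGA	0.226	0.444	0.093	1.99E-08
118	38418823	38440030	21207	GGGGG	0.658	0.903	0.508	2.73E-08
119	38446577	38523760	77183	GAGAAAAGAGAG	0.138	0.306	0.035	1.58E-07
120	38539025	38550947	11922	CAG	0.474	0.167	0.661	3.58E-11
125	38878307	38896758	18451	AAGGAAGAG	0.742	0.958	0.61	1.03E-07
131	38975737	39004699	28962	AAG	0.531	0.763	0.39	5.45E-07
137	39262981	39267121	4140	AAAG	0.5	0.764	0.339	1.33E-08
137	39262981	39267121	4140	GGGA	0.489	0.236	0.644	4.84E-08
138	39270125	39326031	55906	AGAAAGAACGAGAGGAACA	0.474	0.75	0.305	2.55E-09
139	39337264	39367991	30727	CCGGGAAAAGCGA	0.121	0.278	0.025	2.30E-07
143	39469953	39508807	38854	GGGAGGGCAGCGGGAGGAGA	0.1	0.264	0	4.06E-09
179	40558060	40588890	30830	AGAAG	0.405	0.681	0.237	1.56E-09
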