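rs	gene	func	position	alleles	or_btl	post_prob	or_logistic	p_trend	aucrf_selected
rs3087455	CASP3	intronic	4q35.1	A/C	0.81	96.07	0.66	0.002	1
rs10999426	PRF1	intronic	10q22.1	A/G	1.20	93.33	1.36	0.025	1
rs1494555	IL7R	non_synonymous_coding	5p13.2	G/A	1.19	92.30	1.43	0.015	1
rs2230806	ABCA1	non_synonymous_coding	9q31.1	G/A	1.19	92.05	1.38	0.029	1
rs3091312	CCR3	downstream	3p21.31	A/T	0.86	90.93	0.69	0.013	0
rs8192284	IL6R	non_synonymous_coding	1q21.3	A/G	0.88	90.35	0.74	0.022	1
rs2236757	IFNAR2	intronic	21q22.11	A/G	1.16	89.77	1.43	0.015	0
rs8193036	IL17A	upstream	6p12.2	C/T	0.88	88.50	0.74	0.048	0
rs710459	MASP1	intronic	3q27.3	C/T	1.14	88.17	1.23	0.113	1
rs4765621	SCARB1	intronic	12q24.31	G/A	0.89	87.88	0.78	0.063	1
rs150126	MAP3K7	intronic	6q15	G/A	0.88	87.74	0.68	0.011	0
rs3789928	BLNK	intronic	10q24.1	G/C	0.88	87.63	0.78	0.069	0
rs7209435	MAP3K3	intronic	17q23.3	T/C	1.13	86.29	1.29	0.095	0
rs2020902	CASP9	splice_site	1p36.21	T/C	0.88	86.19	0.61	0.007	0
rs899729	IL17C	upstream	16q24.3	C/A	1.12	86.06	1.22	0.132	1
rs7101	FOS	5_prime_UTR	14q24.3	C/T	0.89	85.93	0.71	0.023	0
rs12357751	BLNK	intronic	10q24.1	C/T	1.14	85.67	1.36	0.040	0
rs3804099	TLR2	synonymous_coding	4q31.1	T/C	1.13	84.97	1.27	0.072	1
rs2737191	TLR4	upstream	9q33.1	A/G	1.12	84.53	1.28	0.088	0
rs4791489	MAP2K4	downstream	17p12	C/T	0.91	84.52	0.80	0.112	1
rs10878176	TBK1	intronic	12q14.2	G/C	0.90	83.88	0.70	0.014	0
rs17226566	LY96	intronic	8q21.11	T/C	0.90	83.47	0.77	0.108	0
rs744120	BIRC5	upstream	17q25.3	C/G	0.90	83.27	0.69	0.014	0
rs723279	SOCS6	intronic	18q22.2	G/A	1.12	83.16	1.28	0.097	0
rs13428	PARP4	non_synonymous_coding	13q12.12	G/C	1.11	83.11	1.26	0.094	0
rs11046349	AICDA	3_prime_UTR	12p13.31	T/G	0.91	82.17	0.60	0.014	0
rs11602147	BIRC3	intronic	11q22.2	C/G	1.10	81.98	1.23	0.148	0
rs1063169	FOS	intronic	14q24.3	G/T	1.12	81.88	1.56	0.018	0
rs2569190	CD14_IK	5_prime_UTR	5q31.3	A/G	0.92	81.83	0.75	0.025	1
rs5498	ICAM1	coding_unknown	19q13.2	A/G	1.10	81.24	1.25	0.087	1
rs17461269	IL15	intronic	4q31.21	T/A	0.91	81.22	0.76	0.072	0
rs3765535	ABCC4	intronic	13q32.1	A/G	1.12	81.21	1.41	0.091	0
rs11888	JAK3	3_prime_UTR	19p13.11	T/C	0.92	81.15	0.84	0.212	0
rs10882755	BLNK	intronic	10q24.1	A/G	1.13	80.76	1.41	0.058	0
rs7939734	FADD	upstream	11q13.3	T/A	1.10	80.75	1.22	0.135	1
rs8049804	IL21R	intergenic	17q22	A/C	1.10	80.33	1.18	0.239	0
rs4871857	TNFRSF10A	non_synonymous_coding	8p21.3	G/C	0.93	80.22	0.80	0.082	0
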