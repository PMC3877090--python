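rs	gene	func	position	alleles	or_btl	post_prob	or_logistic	p_trend	aucrf_selected
rs696	NFKBIA	3_prime_UTR	14q13.2	A/G	1.16	79.97	2.47	0.004	1
rs2647396	BCL10	intronic	1p22.3	C/T	0.89	79.65	0.40	0.011	1
rs10999426	PRF1	intronic	10q22.1	A/G	1.15	78.67	2.11	0.019	1
rs1800890	IL10	upstream	1q32.1	A/T	1.13	76.48	2.26	0.019	1
rs4791489	MAP2K4	downstream	17p12	C/T	0.91	76.87	0.49	0.030	1
rs812606	MAP3K7	intronic	6q15	C/T	1.13	76.37	2.68	0.005	1
rs1061217	SLAMF1	3_prime_UTR	1q23.3	T/C	1.12	75.89	1.73	0.077	1
rs11188660	BLNK	intronic	10q24.1	C/T	1.12	75.66	2.56	0.004	1
rs20432	PTGS2	intronic	1q31.1	T/G	0.91	75.17	0.28	0.003	0
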