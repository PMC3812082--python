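# Published spontaneous mutation rates for the H3K56 acetylation/deacetylation
# mutant panel (reference values used by the reconciliation stage).
# Absolute rates and CI bounds are in units of 1e-8 mutations per cell per
# generation; printed_relative is the relative rate as printed alongside them.
# background names the wild-type row each relative rate is computed against.
# upper_bound=1 marks "<" detection-limit entries.
table	genotype	background	reporter	rate_1e8	ci_low_1e8	ci_high_1e8	printed_relative	upper_bound
1	wild type E35	wild type E35	CAN1	27	23	49	1	0
1	wild type E35	wild type E35	his7-2	0.6	0.4	1.0	1	0
1	hst3 hst4 (E35)	wild type E35	CAN1	690	470	850	25	0
1	hst3 hst4 (E35)	wild type E35	his7-2	16	8	32	27	0
1	wild type BY4742	wild type BY4742	CAN1	17	14	25	1	0
1	hst3 hst4 (BY4742)	wild type BY4742	CAN1	500	390	600	28	0
1	wild type	wild type	CAN1	19	16	24	1	0
1	wild type	wild type	his7-2	0.6	0.6	1.0	1	0
1	hst3	wild type	CAN1	33	25	42	2	0
1	hst3	wild type	his7-2	1.2	0.9	1.5	2	0
1	hst4	wild type	CAN1	25	14	41	1	0
1	hst4	wild type	his7-2	1.0	0.5	1.6	2	0
1	hst3 hst4	wild type	CAN1	480	420	570	25	0
1	hst3 hst4	wild type	his7-2	14	11	23	23	0
1	rtt109	wild type	CAN1	37	29	51	2	0
1	rtt109	wild type	his7-2	5.1	2.6	7.4	9	0
1	hst3 hst4 rtt109	wild type	CAN1	30	19	33	2	0
1	hst3 hst4 rtt109	wild type	his7-2	3.1	2.2	5.2	5	0
1	H3K56R	wild type	CAN1	39	29	56	2	0
1	H3K56R	wild type	his7-2	5.7	3.4	9.4	10	0
1	hst3 hst4 H3K56R	wild type	CAN1	32	28	55	2	0
1	hst3 hst4 H3K56R	wild type	his7-2	7.0	3.3	9.6	12	0
1	H3K56Q	wild type	CAN1	84	59	160	4	0
1	H3K56Q	wild type	his7-2	5.8	4.3	9	10	0
1	hst3 hst4 H3K56Q	wild type	CAN1	120	83	150	6	0
1	hst3 hst4 H3K56Q	wild type	his7-2	5.0	3.8	7.3	8	0
1	hst3 H3K56Q	wild type	CAN1	85	76	140	5	0
1	hst3 H3K56Q	wild type	his7-2	5.6	3.9	10	9	0
1	hst1 H3K56Q	wild type	CAN1	96	77	130	5	0
1	hst1 H3K56Q	wild type	his7-2	9.3	5.9	15	16	0
1	hst1	wild type	CAN1	19	16	28	1	0
1	hst1	wild type	his7-2	0.6	0.6	0.9	1	1
1	hst2	wild type	CAN1	25	16	32	1	0
1	hst2	wild type	his7-2	0.7	0.4	1.2	1	0
1	hst1 hst3	wild type	CAN1	19	10	25	1	0
1	hst1 hst3	wild type	his7-2	1.4	0.6	2.2	2	0
1	hst1 hst2 hst3	wild type	CAN1	19	15	29	1	0
1	hst1 hst2 hst3	wild type	his7-2	0.5	0.4	0.7	1	0
1	hst1 hst2 hst4	wild type	CAN1	15	11	24	1	0
1	hst1 hst2 hst4	wild type	his7-2	0.8	0.6	1.0	1	0
1	hst3 hst4 hst1	wild type	CAN1	1100	960	1500	58	0
1	hst3 hst4 hst1	wild type	his7-2	31	29	38	52	0
1	hst3 hst4 hst1 hst2	wild type	CAN1	1600	1100	1900	86	0
1	hst3 hst4 hst1 hst2	wild type	his7-2	35	28	53	58	0
1	hst3 hst4 hst2	wild type	CAN1	680	440	960	36	0
1	hst3 hst4 hst2	wild type	his7-2	18	11	32	30	0
2	asf1	wild type	CAN1	35	26	49	2	0
2	asf1	wild type	his7-2	8.5	6.3	10.2	14	0
2	rtt109 H3K56R	wild type	CAN1	44	34	67	2	0
2	rtt109 H3K56R	wild type	his7-2	6.7	3.6	11.7	11	0
2	htz1	wild type	CAN1	18	12	32	1	0
2	htz1	wild type	his7-2	0.8	0.7	1.7	1	0
2	swr1	wild type	CAN1	16	12	24	1	0
2	swr1	wild type	his7-2	0.7	0.5	2.2	1	0
2	msh2	wild type	CAN1	620	450	830	33	0
2	msh2	wild type	his7-2	140	110	170	230	0
2	msh2 rtt109	wild type	CAN1	1600	1000	2200	84	0
2	msh2 rtt109	wild type	his7-2	230	170	290	390	0
2	msh2 H3K56R	wild type	CAN1	1600	1000	2400	83	0
2	msh2 H3K56R	wild type	his7-2	510	350	610	840	0
2	msh2 asf1	wild type	CAN1	1900	1300	3700	100	0
2	msh2 asf1	wild type	his7-2	590	430	920	990	0
2	pol2-4	wild type	CAN1	75	56	100	4	0
2	pol2-4	wild type	his7-2	3.9	3.5	5	7	0
2	pol2-4 rtt109	wild type	CAN1	170	110	280	9	0
2	pol2-4 rtt109	wild type	his7-2	16	9	24	27	0
2	pol2-4 H3K56R	wild type	CAN1	370	240	520	20	0
2	pol2-4 H3K56R	wild type	his7-2	39	31	56	65	0
2	pol2-4 asf1	wild type	CAN1	300	260	530	15	0
2	pol2-4 asf1	wild type	his7-2	19	17	27	32	0
2	pol3-5DV	wild type	CAN1	150	130	190	7	0
2	pol3-5DV	wild type	his7-2	9.7	8	16	16	0
2	pol3-5DV rtt109	wild type	CAN1	280	200	430	15	0
2	pol3-5DV rtt109	wild type	his7-2	20	15	24	33	0
2	pol3-5DV H3K56R	wild type	CAN1	600	470	920	32	0
2	pol3-5DV H3K56R	wild type	his7-2	38	23	48	63	0
2	pol3-5DV asf1	wild type	CAN1	620	330	800	32	0
2	pol3-5DV asf1	wild type	his7-2	34	24	42	57	0
3	rev3	wild type	CAN1	11	8	17	0.6	0
3	rev3	wild type	his7-2	0.6	0.6	0.7	1	0
3	rev3 hst3 hst4	wild type	CAN1	500	420	830	26	0
3	rev3 hst3 hst4	wild type	his7-2	17	14	20	28	0
3	rtt101	wild type	CAN1	36	25	71	2	0
3	rtt101	wild type	his7-2	3.4	2	7.8	6	0
3	rtt101 hst3 hst4	wild type	CAN1	41	36	60	2	0
3	rtt101 hst3 hst4	wild type	his7-2	2.3	1.9	7.3	4	0
3	ctf18	wild type	CAN1	25	19	37	1	0
3	ctf18	wild type	his7-2	1.7	0.8	2.8	3	0
3	ctf18 hst3 hst4	wild type	CAN1	120	100	180	6	0
3	ctf18 hst3 hst4	wild type	his7-2	4.6	2.6	9.2	8	0
3	rev3 rtt109	wild type	CAN1	18	16	22	1	0
3	rev3 rtt109	wild type	his7-2	2.6	1.6	3.1	4	0
3	rad51	wild type	CAN1	370	290	520	19	0
3	rad51	wild type	his7-2	4.6	3.7	5.9	8	0
3	rad51 rtt109	wild type	CAN1	410	250	430	22	0
3	rad51 rtt109	wild type	his7-2	4.4	2.8	8.3	8	0
3	rad52	wild type	CAN1	390	310	480	21	0
3	rad52	wild type	his7-2	4.0	3.2	5.7	7	0
3	rad52 rtt109	wild type	CAN1	390	280	680	21	0
3	rad52 rtt109	wild type	his7-2	5.5	1.6	8.1	9	0
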