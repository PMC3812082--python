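# Cells of the published rate tables whose printed relative rate cannot be
# recovered from the printed absolute rates under the documented rounding
# convention.  In each case the printed relative was evidently derived from
# the unrounded absolute rate (not published) or rounded up to 1 for weak
# sub-unity values; the computed column is the value implied by the printed
# absolute rates.
table	genotype	reporter	computed	printed
1	hst3 hst4 (E35)	CAN1	26	25
1	hst3 hst4 (BY4742)	CAN1	29	28
1	hst1 hst2 hst3	his7-2	0.8	1
1	hst1 hst2 hst4	CAN1	0.8	1
1	hst3 hst4 hst1 hst2	CAN1	84	86
2	htz1	CAN1	0.9	1
2	swr1	CAN1	0.8	1
2	msh2 rtt109	his7-2	380	390
2	msh2 H3K56R	CAN1	84	83
2	msh2 H3K56R	his7-2	850	840
2	msh2 asf1	his7-2	980	990
2	pol2-4 H3K56R	CAN1	19	20
2	pol2-4 asf1	CAN1	16	15
2	pol3-5DV	CAN1	8	7
2	pol3-5DV asf1	CAN1	33	32
3	rev3 rtt109	CAN1	0.9	1
3	rad51 rtt109	his7-2	7	8
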