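primer_pair	amplicon_bp	region	haplotype	n	c1	c2	c3	c4	c5	c6	c7	c8	c9	c10	c11
MLT_C1-MLT_C4	150	trnG_intron	A	14	2	10	0	2	0	0	0	0	0	0	0
MLT_C1-MLT_C4	150	trnG_intron	B	16	11	0	4	0	1	0	0	0	0	0	0
MLT_C1-MLT_C4	150	trnG_intron	C	11	10	1	0	0	0	0	0	0	0	0	0
MLT_C1-MLT_C4	150	trnG_intron	D	11	8	1	3	0	0	0	0	0	0	0	0
MLT_C3-MLT_C4	236	trnG_intron	A	14	14	0	0	0	0	0	0	0	0	0	0
MLT_C3-MLT_C4	236	trnG_intron	B	16	9	6	1	0	0	0	0	0	0	0	0
MLT_C3-MLT_C4	236	trnG_intron	C	12	4	7	0	1	0	0	0	0	0	0	0
MLT_C3-MLT_C4	236	trnG_intron	D	14	11	3	0	0	0	0	0	0	0	0	0
MLT_M1-MLT_M2	170	petL-psbE	A	15	0	14	1	0	0	0	0	0	0	0	0
MLT_M1-MLT_M2	170	petL-psbE	B	16	15	0	0	1	0	0	0	0	0	0	0
MLT_M1-MLT_M2	170	petL-psbE	C	14	0	1	13	0	0	0	0	0	0	0	0
MLT_M1-MLT_M2	170	petL-psbE	D	16	15	0	0	1	0	0	0	0	0	0	0
MLT_S1-MLT_S2	217	atpI-atpH	A	12	0	0	12	0	0	0	0	0	0	0	0
MLT_S1-MLT_S2	217	atpI-atpH	B	15	15	0	0	0	0	0	0	0	0	0	0
MLT_S1-MLT_S2	217	atpI-atpH	C	11	0	0	0	11	0	0	0	0	0	0	0
MLT_S1-MLT_S2	217	atpI-atpH	D	14	0	14	0	0	0	0	0	0	0	0	0
MLT_S1-MLT_S4	527	atpI-atpH	A	14	14	0	0	0	0	0	0	0	0	0	0
MLT_S1-MLT_S4	527	atpI-atpH	B	10	0	0	0	0	8	2	0	0	0	0	0
MLT_S1-MLT_S4	527	atpI-atpH	C	14	14	0	0	0	0	0	0	0	0	0	0
MLT_S1-MLT_S4	527	atpI-atpH	D	14	0	0	12	0	0	0	2	0	0	0	0
MLT_S1-MLT_S4	527	atpI-atpH	E	16	0	16	0	0	0	0	0	0	0	0	0
MLT_S1-MLT_S4	527	atpI-atpH	F	14	0	0	0	10	0	0	0	2	2	0	0
MLT_S3-MLT_S4	310	atpI-atpH	A	15	0	15	0	0	0	0	0	0	0	0	0
MLT_S3-MLT_S4	310	atpI-atpH	B	12	0	0	0	11	0	0	1	0	0	0	0
MLT_S3-MLT_S4	310	atpI-atpH	C	11	0	0	0	0	10	1	0	0	0	0	0
MLT_S3-MLT_S4	310	atpI-atpH	D	16	16	0	0	0	0	0	0	0	0	0	0
MLT_S3-MLT_S4	310	atpI-atpH	E	14	0	0	13	0	0	0	0	0	1	0	0
MLT_U1-MLT_U2	345	ndhA_intron	A	16	16	0	0	0	0	0	0	0	0	0	0
MLT_U1-MLT_U2	345	ndhA_intron	B	11	0	0	0	8	0	0	3	0	0	0	0
MLT_U1-MLT_U2	345	ndhA_intron	C	15	0	14	0	0	0	0	0	0	0	0	1
MLT_U1-MLT_U2	345	ndhA_intron	D	16	0	0	0	0	10	3	0	2	1	0	0
MLT_U1-MLT_U2	345	ndhA_intron	E	12	0	0	11	0	0	0	0	0	0	1	0
MLT_V1-MLT_V2	340	rpl32-trnL	A	14	12	2	0	0	0	0	0	0	0	0	0
MLT_V1-MLT_V2	340	rpl32-trnL	B	11	0	1	10	0	0	0	0	0	0	0	0
MLT_V1-MLT_V2	340	rpl32-trnL	C	13	12	1	0	0	0	0	0	0	0	0	0
MLT_V1-MLT_V2	340	rpl32-trnL	D	10	0	10	0	0	0	0	0	0	0	0	0
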