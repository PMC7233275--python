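primer_pair	haplotype	sensitivity	specificity	accuracy
MLT_C1-MLT_C4	A	71	94	88
MLT_C1-MLT_C4	B	69	44	52
MLT_C1-MLT_C4	C	91	49	58
MLT_C1-MLT_C4	D	73	44	50
MLT_C3-MLT_C4	A	100	43	57
MLT_C3-MLT_C4	B	56	27	36
MLT_C3-MLT_C4	C	58	79	75
MLT_C3-MLT_C4	D	79	36	46
MLT_M1-MLT_M2	A	93	98	97
MLT_M1-MLT_M2	B	94	67	74
MLT_M1-MLT_M2	C	93	98	97
MLT_M1-MLT_M2	D	94	67	74
MLT_S1-MLT_S2	A	100	100	100
MLT_S1-MLT_S2	B	100	100	100
MLT_S1-MLT_S2	C	100	100	100
MLT_S1-MLT_S2	D	100	100	100
MLT_S1-MLT_S4	A	100	79	83
MLT_S1-MLT_S4	B	80	100	98
MLT_S1-MLT_S4	C	100	79	83
MLT_S1-MLT_S4	D	86	100	98
MLT_S1-MLT_S4	E	100	100	100
MLT_S1-MLT_S4	F	71	100	95
MLT_S3-MLT_S4	A	100	100	100
MLT_S3-MLT_S4	B	92	100	95
MLT_S3-MLT_S4	C	91	100	95
MLT_S3-MLT_S4	D	100	100	100
MLT_S3-MLT_S4	E	93	100	95
MLT_U1-MLT_U2	A	100	100	100
MLT_U1-MLT_U2	B	73	100	96
MLT_U1-MLT_U2	C	93	100	99
MLT_U1-MLT_U2	D	63	100	91
MLT_U1-MLT_U2	E	92	100	99
MLT_V1-MLT_V2	A	86	65	71
MLT_V1-MLT_V2	B	91	99	98
MLT_V1-MLT_V2	C	92	66	73
MLT_V1-MLT_V2	D	100	89	92
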