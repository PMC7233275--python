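primer_pair	haplotype_pair	difference_classes	specificity
MLT_C1-MLT_C4	C-D	class2+class2	18
MLT_C1-MLT_C4	B-C	class2	20
MLT_C1-MLT_C4	B-D	class2	29
MLT_C1-MLT_C4	A-C	multi	88
MLT_C1-MLT_C4	A-D	class2+class4	88
MLT_C1-MLT_C4	A-B	multi	93
MLT_C3-MLT_C4	A-D	class4	11
MLT_C3-MLT_C4	A-B	indel8+class4	22
MLT_C3-MLT_C4	B-D	indel8	33
MLT_C3-MLT_C4	B-C	class2+indel8	65
MLT_C3-MLT_C4	C-D	class2	73
MLT_C3-MLT_C4	A-C	class2+class4	83
MLT_M1-MLT_M2	A-C	class2+class1	6
MLT_M1-MLT_M2	B-D	class1+class2	93
MLT_S1-MLT_S4	A-C	indel5	0
MLT_V1-MLT_V2	A-C	indel6+class4+class4	11
MLT_V1-MLT_V2	A-D	indel6+class4	93
MLT_V1-MLT_V2	C-D	class4	96
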