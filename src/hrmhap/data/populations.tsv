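population	latitude	longitude	group	A	B	C	D	E
GAR	-33.96	21.22	Langeberg	0	0	0	24	0
OUT	-33.88	22.4	Outeniqua_W	14	0	0	0	6
BP	-33.91	22.67	Outeniqua_W	15	0	0	0	0
KNYS	-33.92	23.14	Outeniqua_E	15	0	0	0	0
PLETT	-34.06	23.26	Outeniqua_E	16	0	0	0	0
BKB	-33.97	23.65	Tsitsikamma	14	0	4	0	0
LK	-33.87	23.91	Tsitsikamma	9	0	0	0	1
KP	-33.97	24.22	Tsitsikamma	19	5	0	0	0
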