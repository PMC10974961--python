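experiment	x90_3_um	M_kg	n_rpm	Vdot_L_min	T_C_in_C	T_S_out_C	E_M_kJ_kg	SE_uNm	N	x_PCS_nm	PdI
1	4.8	82	1050	20	9	20	2186	0.88	169	127	0.10
2	4.9	62	1050	20	9	22	2795	0.88	232	119	0.12
3	5.4	62	1225	17	10	27	4007	1.17	213	111	0.13
4	5.0	82	875	13	8	18	2134	0.61	195	123	0.11
5	5.1	82	1050	5	10	23	2134	0.88	57	124	0.11
6	5.1	72	1050	17	8	22	2134	0.88	179	121	0.12
7	5.1	72	1050	19	10	21	2134	0.88	156	128	0.12
8	4.8	155	1050	16	9	24	2134	0.88	79	125	0.12
9	4.4	165	1050	16	9	21	2150	0.88	135	127	0.11
10	4.8	165	1050	16	9	21	2150	0.88	133	132	0.12
11	5.9	165	1050	16	9	21	2140	0.88	136	127	0.11
12	5.7	165	1050	16	9	21	2150	0.87	137	132	0.12
13	6.2	175	1050	16	9	20	640	0.87	36	174	0.11
14	6.6	175	1050	16	9	20	2400	0.87	143	129	0.11
15	7.6	175	1050	16	9	20	1400	0.87	80	144	0.12
16	5.3	175	1050	16	9	21	600	0.88	35	173	0.10
17	4.5	175	1050	16	9	21	2400	0.87	152	129	0.13
18	4.2	175	1050	16	9	20	1400	0.88	87	137	0.12
19	7.6	175	1050	16	9	22	1400	0.87	89	142	0.11
20	5.9	175	1050	16	9	21	1400	0.87	89	138	0.12
21	4.5	175	1050	16	9	21	600	0.87	37	172	0.07
22	5.1	175	1050	16	9	21	2400	0.87	156	127	0.11
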