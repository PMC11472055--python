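pair_id	age	sex	depth_twin1	depth_twin2	concordance_rate_pct	n_discordant	n_exonic
1	24	M	25.0	24.5	99.7	52	0
2	37	M	25.1	25.2	99.7	63	4
3	82	M	25.5	24.8	99.7	77	2
4	59	M	24.5	24.9	99.7	163	1
5	79	F	25.6	24.8	99.7	70	1
6	77	F	24.9	24.7	99.6	91	1
7	56	M	24.7	24.6	99.6	49	0
8	46	F	25.2	24.5	99.6	68	1
9	54	M	25.0	24.0	99.6	55	0
10	30	M	24.0	24.8	99.6	55	1
11	48	F	24.6	24.4	99.6	67	0
12	67	F	24.2	23.1	99.6	51	0
13	71	M	23.9	24.1	99.6	164	4
14	27	M	24.0	24.4	99.5	71	1
15	32	M	23.8	23.3	99.5	75	0
16	65	M	23.7	24.7	99.5	112	1
17	41	F	23.5	23.4	99.5	86	2
18	36	F	23.9	23.7	99.5	84	1
19	50	M	23.6	23.8	99.5	82	2
20	29	F	24.6	23.9	99.4	73	2
21	40	M	23.4	22.8	99.3	123	0
22	32	F	21.6	23.9	99.3	114	1
23	37	F	22.5	21.9	99.2	140	2
24	24	F	23.7	23.2	98.9	189	0
25	51	F	22.8	22.7	98.9	314	1
26	21	F	23.9	22.4	98.2	633	1
27	62	F	24.6	19.9	98.1	302	0
28	76	M	21.6	22.4	97.7	951	1
29	66	M	23.5	23.4	96.9	618	2
30	74	F	22.3	22.4	96.5	1811	2
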