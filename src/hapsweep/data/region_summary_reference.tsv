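chrom	n_regions	length_bp	n_snps	n_multi
1	18	3549100	67	10
2	34	6581006	44	34
3	27	5892878	105	19
4	16	2450404	45	12
5	8	1845327	27	10
6	10	2590704	43	5
7	4	521393	11	1
8	9	1097043	17	5
9	5	983744	17	2
10	4	1077755	16	9
11	2	116626	2	2
12	7	822135	16	4
13	7	960058	18	3
14	1	57444	2	0
15	6	914153	21	3
16	6	181219	7	3
17	4	578619	9	4
18	10	1669082	27	7
19	2	153579	3	1
22	3	486195	7	2
23	17	1407368	34	11
24	2	286693	3	2
25	1	107671	2	2
26	4	627507	12	2
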