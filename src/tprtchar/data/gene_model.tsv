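# Synthetic NF1 mini-gene exon table. Transcript (c.) exon boundaries of the
# exons carrying or flanking the 18 insertions are taken from the published
# r.-level deletion intervals; the remaining boundaries are evenly
# interpolated. Legacy labels follow the historical NF1 numbering.
index	legacy_label	c_start	c_end
1	1	1	117
2	2	118	234
3	3	235	351
4	4a	352	468
5	4b	469	586
6	4c	587	654
7	5	655	771
8	6	772	888
9	7	889	1062
10	8	1063	1185
11	9	1186	1260
12	10a	1261	1392
13	10b	1393	1516
14	10c	1517	1641
15	11	1642	1721
16	12a	1722	1858
17	12b	1859	1996
18	13	1997	2134
19	14	2135	2271
20	15	2272	2409
21	16	2410	2850
22	17	2851	2990
23	18	2991	3113
24	19a	3114	3197
25	19b	3198	3314
26	20	3315	3450
27	21	3451	3587
28	22	3588	3723
29	23	3724	3860
30	24a	3861	3996
31	24b	3997	4133
32	24c	4134	4269
33	25	4270	4367
34	26	4368	4603
35	27a	4604	4838
36	27b	4839	5074
37	28	5075	5309
38	29	5310	5545
39	30	5546	5749
40	31	5750	5907
41	32	5908	6066
42	33	6067	6224
43	34	6225	6383
44	35	6384	6541
45	36	6542	6700
46	37	6701	6858
47	38	6859	6999
48	39	7000	7126
49	40	7127	7258
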