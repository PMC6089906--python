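1	1	no rank
2	1	domain
3	2	phylum
4	2	phylum
5	3	class
6	4	class
7	5	order
8	6	order
9	7	family
10	8	family
11	9	genus
12	9	genus
13	10	genus
14	11	species
15	11	species
16	12	species
17	13	species
18	14	subspecies
19	15	no rank
20	7	species
21	10	genus
22	13	species
23	12	species
24	13	species
25	14	subspecies
26	2	phylum
27	26	class
28	27	order
29	28	family
30	29	genus
31	30	species
32	30	species
33	31	subspecies
34	3	no rank
35	9	genus
36	35	species
37	16	subspecies
38	8	family
39	38	genus
40	39	species
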