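1	root
2	d1
3	p1
4	p2
5	c1
6	c2
7	o1
8	o2
9	f1
10	f2
11	g1
12	g2
13	g3
14	g1_species1
15	g1_species2
16	g2_species1
17	g3_species1
18	g1_species1_subsp1
19	g1_species2_strainX
20	gapped_species
21	shared_name
22	shared_name
23	g2_species2
24	g3_species2
25	g1_species1_subsp2
26	p3
27	c3
28	o3
29	f3
30	g4
31	g4_species1
32	g4_species2
33	g4_species1_subsp1
34	env_clade
35	g5
36	g5_species1
37	g2_species1_subsp1
38	o2_f4
39	g6
40	g6_species1
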