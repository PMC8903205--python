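# Representative male /a/ vocal tract area function, 44 sections of
# 0.3968 cm from the glottis (section 1) to the lips (section 44).
# Synthetic table constructed from the standard vocal-tract literature
# shape for /a/ (narrow epilarynx and pharynx, wide open oral cavity);
# columns: section index, area (cm^2).
1	0.45
2	0.50
3	0.55
4	0.60
5	0.70
6	0.85
7	1.00
8	1.10
9	1.20
10	1.30
11	1.40
12	1.50
13	1.60
14	1.70
15	1.80
16	1.80
17	1.70
18	1.50
19	1.30
20	1.10
21	1.00
22	1.00
23	1.10
24	1.30
25	1.60
26	2.00
27	2.50
28	3.00
29	3.50
30	4.00
31	4.50
32	5.00
33	5.50
34	6.00
35	6.50
36	7.00
37	7.00
38	6.80
39	6.40
40	6.00
41	5.40
42	4.80
43	4.20
44	3.60
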