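sample	polyploid	her2_estimate	fish3d
1	No	normal
2	Yes	5+
3	Yes	3+
4	No	normal
5	Yes	4+	4-5
6	Yes	3+
7	Yes	3+
8	Yes	4+
9	Yes	3+
10	No	3
11	Yes	3+
12	Yes	5+
13	No	normal
14	No	normal
15	Yes	5+
16	Yes	3+
17	Yes	3+
18	No	3+
19	No	normal
20	No	normal
21	Yes	5+
22	Yes	4
23	Yes	4+
24	Yes	3+
25	No	normal
26	Yes	6+
27	Yes	4+	5-7
28	Yes	4+
29	Yes	4+	4-6
30	Yes	5+
31	Yes	5+	5-7
32	Yes	3+
33	No	normal
34	Yes	5+	5-7
35	No	normal
36	Yes	5+	4-5
37	Yes	3+
38	Yes	3+
39	No	normal
40	No	normal
41	Yes	5+
42	No	normal
43	Yes	UPD(2) or amp	32
44	Yes	5+
45	Yes	8+	8
46	Yes	4+
47	No	normal
48	Yes	5+
49	Yes	25+
50	Yes	5+
51	No	3
52	No	3
53	Yes	7+
54	Yes	7+
55	Yes	7+	5-6
56	Yes	12+
57	No	normal
58	Yes	12+
59	Yes	6+
60	No	normal
61	Yes	8+
62	Yes	8+
63	No	normal
64	Yes	7+
65	Yes	9+
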