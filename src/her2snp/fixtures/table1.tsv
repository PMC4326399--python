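sample	ihc	ihc_revised	fish	fish_revised	seg_cn	relation	status
1	0				1.98	balance	normal
2	0				2.35	HER2plus	amp
3	0		1.92		1.81	balance	normal
4	0				2.06	balance	normal
5	0				2.04	balance	normal
6	0				1.72	centplus	del
7	0				1.67	balance	del
8	0				1.83	balance	normal
9	0				1.51	centplus	del
10	0				2.51	balance	amp
11	0				1.78	balance	del
12	0				1.85	balance	normal
13	1				1.97	balance	normal
14	1				2.08	balance	normal
15	1		0.83		2.33	balance	amp
16	1		0.80		1.70	balance	del
17	1		0.80		1.80	centplus	normal
18	1		0.86		2.49	balance	amp
19	1				2.06	balance	normal
20	1				2.09	balance	normal
21	1				1.96	balance	normal
22	1				1.97	balance	normal
23	1				2.13	balance	normal
24	1				1.90	balance	normal
25	1				1.87	balance	normal
26	1				4.46	balance	amp
27	1				2.34	balance	amp
28	2		1.41		2.45	balance	amp
29	2		1.54		2.16	balance	normal
30	2		3.05		2.04	balance	normal
31	2		2.69		2.48	balance	amp
32	2		2.42		1.75	centplus	del
33	2		1.73		1.99	balance	normal
34	2		2.65		1.92	balance	normal
35	2		1.50		1.91	balance	normal
36	2		1.57		2.00	balance	normal
37	2		1.68		1.79	balance	del
38	2		1.90		1.84	balance	normal
39	2		1.60		2.05	balance	normal
40	2		1.58		1.89	balance	normal
41	2		2.13		2.73	balance	amp
42	2		1.54		2.04	balance	normal
43	2		1.82		1.54	balance	del
44	2		1.90		1.77	balance	del
45	2		1.66		2.33	balance	amp
46	2		1.48		2.04	balance	normal
47	2		1.73		1.98	balance	normal
48	2		1.67		2.36	balance	amp
49	2	3	0.93	8.8	11.10	HER2plus	amp
50	2		1.81		2.04	balance	normal
51	2		1.58		2.65	HER2plus	amp
52	2		1.60		2.23	balance	amp
53	2		2.27		8.03	HER2plus	amp
54	2		1.87		2.91	balance	amp
55	2		1.24		2.66	balance	amp
56	2		7.38		7.01	HER2plus	amp
57	2		1.00		1.88	balance	normal
58	2		8.60		7.98	HER2plus	amp
59	2		3.24		3.18	HER2plus	amp
60	3	1		1.65	2.00	balance	normal
61	3		4.11		5.28	HER2plus	amp
62	3		7.00		4.58	HER2plus	amp
63	3	2		1.50	2.05	balance	normal
64	3				3.15	HER2plus	amp
65	3		1.35		3.75	HER2plus	amp
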