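p1_cutoff	p2_cutoff	n_concordant	n_discordant	n_snps	proportion	or_ft	p_ft
1.0	1.0	30790	28398	59188	0.52	1.18	8.77e-23
0.9	0.9	27540	25213	52753	0.52	1.19	4.11e-24
0.8	0.8	24222	21971	46193	0.52	1.22	1.30e-25
0.7	0.7	20842	18665	39507	0.53	1.25	6.60e-28
0.6	0.6	17474	15458	32932	0.53	1.28	1.23e-28
0.5	0.5	14218	12383	26601	0.53	1.32	2.69e-29
0.4	0.4	10973	9415	20388	0.54	1.36	1.31e-27
0.3	0.3	7804	6510	14314	0.55	1.44	3.21e-27
0.2	0.2	4771	3855	8626	0.55	1.53	6.92e-23
0.1	0.1	1946	1496	3442	0.57	1.69	2.06e-14
0.05	0.05	804	579	1383	0.58	1.92	2.23e-09
0.01	0.01	85	43	128	0.66	3.61	7.20e-04
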