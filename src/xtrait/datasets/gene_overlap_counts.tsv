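threshold	disc_raw	disc_eff	targ_raw	targ_eff	raw_overlap	eff_overlap	disc_eff_total	targ_eff_total	binomial_p
0.01	481	386	587	450	17	15	17104	17046	0.08259
0.05	1749	1430	1871	1467	196	171	17104	17046	9.83e-06
0.1	2966	2433	3239	2579	493	420	17104	17046	1.85e-03
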