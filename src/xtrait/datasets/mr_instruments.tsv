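snp_id	effect_allele	other_allele	beta_exposure	se_exposure	p_exposure	beta_outcome	se_outcome	p_outcome	wald_ratio	f_stat	se_ratio	p_ratio
rs10167914	A	G	-0.11	0.02	1.10e-09	0.01	0.01	0.27	-0.11	37.27	0.10	0.27
rs11674184	T	G	0.12	0.01	2.67e-17	-0.02	0.01	0.16	-0.13	71.40	0.09	0.16
rs12037376	A	G	0.15	0.02	8.87e-17	0.01	0.01	0.35	-0.09	68.97	0.10	0.35
rs12700667	A	G	0.10	0.02	9.08e-10	0.01	0.01	0.60	-0.07	37.64	0.13	0.61
rs1537377	T	C	-0.09	0.01	1.33e-10	0.00	0.01	0.83	0.03	41.53	0.12	0.83
rs1903068	A	G	0.10	0.01	1.04e-11	0.01	0.01	0.32	0.11	46.28	0.11	0.32
rs4762326	T	C	0.08	0.01	2.20e-09	-0.01	0.01	0.31	0.14	35.55	0.13	0.31
rs6546324	A	C	0.08	0.01	3.01e-08	-0.01	0.01	0.42	0.11	30.56	0.14	0.42
rs71575922	C	G	-0.11	0.02	2.02e-08	-0.01	0.01	0.35	-0.12	31.41	0.13	0.35
rs74485684	T	C	0.11	0.02	2.00e-08	0.04	0.01	0.01	0.36	31.55	0.13	0.01
rs760794	T	C	0.09	0.01	1.79e-10	-0.02	0.01	0.07	-0.22	40.43	0.12	0.07
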