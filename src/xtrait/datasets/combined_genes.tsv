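gene	chrom	start	stop	gene_p_endometriosis	top_snp_endometriosis	top_snp_p_endometriosis	gene_p_migraine	top_snp_migraine	top_snp_p_migraine	fcp
ARL14EP	11	30344648	30359165	1.00e-06	rs4071559	5.60e-08	5.54e-02	rs4071559	5.97e-03	9.81e-07
TRIM32	9	119449580	119463579	2.76e-02	rs11793648	3.14e-03	5.00e-06	rs76973802	7.15e-07	2.32e-06
SLC35G6	17	7384720	7386383	1.59e-03	rs9891297	3.09e-04	9.40e-05	rs8065577	2.21e-05	2.50e-06
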