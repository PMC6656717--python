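rsid	gene	risk_allele	other_allele	ref_freq	ref_n
rs900000001	BDNF	A	G	0.366	5008
rs13078807	CADM2	C	T	0.487	5008
rs900000002	FANCL	C	T	0.629	5008
rs2112347	FLJ35779	A	T	0.408	5008
rs900000003	FTO	T	C	0.708	5008
rs900000004	GNPDA2	G	A	0.529	5008
rs900000005	HOXC13	G	C	0.557	5008
rs29941	KCTD15	G	A	0.489	5008
rs900000006	LRP1B	G	T	0.705	5008
rs900000007	LRRN6C	A	C	0.315	5008
rs1294421	LY86	C	A	0.246	5008
rs900000008	MAP2K5	T	G	0.223	5008
rs900000009	NFE2L3	T	G	0.382	5008
rs10150332	NRXN3	G	A	0.410	5008
rs900000010	PRKD1	T	C	0.258	5008
rs900000011	RBJ	G	A	0.653	5008
rs4929949	RPL27A	G	C	0.642	5008
rs9491696	RSPO3	A	T	0.242	5008
rs900000012	SEC16B	T	A	0.568	5008
rs7359397	SH2B1	T	C	0.282	5008
rs900000013	TFAP2B	T	A	0.648	5008
rs900000014	TMEM18	G	A	0.565	5008
rs900000015	TNNI3K	C	T	0.290	5008
rs900000016	VEGFA	A	C	0.511	5008
rs900000017	ZNRF3-KREMEN1	C	T	0.385	5008
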