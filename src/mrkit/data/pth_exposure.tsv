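rsid	chr	gene	effect_allele	eaf	beta	se	pval
rs6127099	20	CYP24A1	T	0.34	0.07	0.003	2.4e-72
rs4074995	5	RGS14	G	0.71	0.03	0.003	3.3e-23
rs219779	21	CLDN14	G	0.75	0.04	0.003	8.9e-22
rs4443100	22	RTDR1	G	0.32	0.02	0.003	4.1e-11
rs73186030	3	CASR	T	0.14	0.03	0.004	1.2e-9
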