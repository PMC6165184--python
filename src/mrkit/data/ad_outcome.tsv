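rsid	chr	effect_allele	beta	se	pval
rs6127099	20	T	0.028	0.019	0.155
rs4074995	5	G	0.012	0.018	0.482
rs219779	21	G	0.023	0.018	0.202
rs4443100	22	G	0.005	0.017	0.773
rs73186030	3	T	-0.032	0.022	0.151
rs3755967	4	C	-0.036	0.017	0.034
rs117913124	11	G	-0.057	0.065	0.378
rs12785878	11	T	-0.022	0.018	0.208
rs10741657	11	A	-0.011	0.016	0.492
rs17216707	20	T	-0.045	0.022	0.038
rs1968487	12	T	-0.006	0.016	0.691
rs8018720	14	G	-0.012	0.021	0.584
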