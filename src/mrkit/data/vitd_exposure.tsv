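rsid	chr	gene	effect_allele	eaf	beta	se	pval	unit
rs3755967	4	GC	C	0.72	0.089	0.002	4.74e-343	ln_trait
rs117913124	11	CYP2R1	G	0.975	0.430	0.020	1.50e-88	sd_of_ln_trait
rs12785878	11	DHCR7	T	0.75	0.036	0.002	3.80e-62	ln_trait
rs10741657	11	CYP2R1	A	0.40	0.031	0.002	2.05e-46	ln_trait
rs17216707	20	CYP24A1	T	0.79	0.026	0.003	8.14e-23	ln_trait
rs10745742	12	AMDHD1	T	0.40	0.017	0.002	1.88e-14	ln_trait
rs8018720	14	SEC23A	G	0.18	0.017	0.003	4.72e-9	ln_trait
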