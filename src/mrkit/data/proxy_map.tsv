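target_rsid	proxy_rsid	r2
rs10745742	rs1968487	1.0
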