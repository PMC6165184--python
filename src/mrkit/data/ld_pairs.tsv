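rsid1	rsid2	r2
rs117913124	rs10741657	0.03
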