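group	mean_permil	sd_permil	n
exposed_fertilized	-5.501	0.717	3
unexposed_fertilized	-6.083	0.336	3
exposed_unfertilized	2.198	0.213	3
unexposed_unfertilized	2.169	0.261	3
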