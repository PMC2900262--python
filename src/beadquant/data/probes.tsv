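id	sequence	length_nt	target_mirna	parent_id	mismatch_count	bead_region
miR-23a	GGAAATCCCTGGCAATGTGAT	21	hsa-miR-23a		0	1
miR-27a	GCGGAACTTAGCCACTGTGAA	21	hsa-miR-27a		0	21
miR-27a-1MM	GCGGAACTAAGCCACTGTGAA	21	hsa-miR-27a	miR-27a	1
miR-27a-2MM	GCGGAAGTTAGCCACTGAGAA	21	hsa-miR-27a	miR-27a	2
miR-199a	GAACAGGTAGTCTGAACACTGGG	23	hsa-miR-199a		0	51
miR-199a-1MM	GAACAGGTAGTCTGAAGACTGGG	23	hsa-miR-199a	miR-199a	1
miR-199a-2MM	GATCAGGTAGTGTGAACACTGGG	23	hsa-miR-199a	miR-199a	2
Spike 18	CATTGCCACAATCAAGACTAAGA	23	spike-18		0	57
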