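name	sv_type	interval	read_pairs	reported_size_kb	disrupted_gene
family1_chr3_duplication	duplication	chr3:50382561–50403806	22	21	CACNA2D2
family2_znf423_deletion	deletion	chr16:49741265–49760865	17	19.6	ZNF423
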