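gene	hgvs_c	hgvs_c_alt	intron	ds_ag	ds_dg	delta_esrseq	abs_diff	outcome
ATM	c.1899-123A>G	.	12	0.74	0.71	0.633	1.217	pseudoexon
ATM	c.2466+1552G>C	.	16	0.93	0.69	-0.144	1.816	pseudoexon
ATM	c.8850+2029A>G	.	61	0.22	0.16	-0.187	0.765	pseudoexon
FAM175A	c.476+158G>T	c.476+156G>T	5	0.17	0.22	0.559	0.591	pseudoexon
MUTYH	c.998-27G>A	.	11	0.41	0.05	0.344	1.000	intron_retention
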