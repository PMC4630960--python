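snp_id	chromosome	group	allele_ref	allele_alt	uns_ref	uns_alt	orientation	as_read	ploidy	maf	allelic_or
rs1016343	8	quadruplex	C	T	TTCCCTCCCA	TTCCCTCTCA	reverse	false	2	0.21	1.25
rs10993994	10	quadruplex	C	T	TGACGTCGAA	TGATGTCGAA	forward	true	2	0.47	1.23
rs16901979	8	quadruplex	A	C	ATCTGGCAAA	CTCTGGCAAA	forward	true	2	0.18	1.44
rs5945619	X	quadruplex	C	T	ACTCCCGCCG	ACTCCCGCTG	reverse	false	1	0.26	1.23
rs10896449	11	quintuplex	A	G	GCTGAAAATT	GCTGAAAGTT	reverse	false	2	0.40	0.84
rs1859962	17	quintuplex	T	G	TGATGAACAC	GGATGAACAC	forward	true	2	0.39	1.19
rs4242382	8	quintuplex	A	G	CCACAGGCCC	CCGCAGGCCC	forward	true	2	0.16	1.40
rs4430796	17	quintuplex	G	A	GATGCTGCAT	AATGCTGCAT	forward	true	2	0.46	0.80
rs6983267	8	quintuplex	G	T	TGAAAGGCAC	TGAAAGTCAC	reverse	false	2	0.43	0.81
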