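patient_id	sex	rs1016343	rs10993994	rs16901979	rs5945619	rs10896449	rs1859962	rs4242382	rs4430796	rs6983267
1	M	C/C	T/T	C/C	T	G/G	G/G	G/G	A/A	G/T
2	M	C/C	C/C	C/C	T	A/G	T/T	G/G	A/A	G/T
3	M	C/C	C/C	C/C	C	A/G	T/T	G/G	G/G	G/T
4	M	C/C	C/C	C/C	T	A/G	T/G	G/G	A/A	G/G
5	M	C/C	C/T	C/C	T	G/G	T/T	G/G	G/A	T/T
6	M	T/T	C/T	C/C	T	A/G	T/T	G/G	G/A	T/T
7	M	C/C	C/T	C/C	T	A/G	T/G	G/G	G/A	G/G
8	M	C/T	C/T	A/A	T	A/A	T/T	G/G	A/A	G/T
9	M	C/C	C/C	C/C	C	G/G	T/T	A/G	G/A	T/T
10	M	C/C	C/C	C/C	T	A/G	G/G	G/G	G/A	G/T
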