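marker	chrom	pos	A	B	C	D	E
S1	1	100	0	0	H	H	1
S2	1	200	0	0	1	H	1
S3	1	300	1	1	0	0	0
S4	1	400	1	0	0	0	0
S5	1	500	0	1	0	0	0
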