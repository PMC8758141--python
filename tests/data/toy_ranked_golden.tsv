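mirna_id	N	M	D	O	overlap_genes	p_value	p_adjusted
MIR-A	10	3	2	2	G01,G02	0.066666666666666638	0.19999999999999993
MIR-B	10	4	2	1	G01	0.66666666666666696	1
MIR-C	10	5	2	0		1	1
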