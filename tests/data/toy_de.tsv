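gene	log2FoldChange	pvalue	padj
G01	-1.0	0.001	0.01
G02	-2.0	0.005	0.05
G03	1.0	0.001	0.01
G04	-0.5	0.15	0.2
G05	0.1	0.6	0.8
G06	-0.2	0.5	0.8
G07	0.3	0.4	0.8
G08	-0.1	0.7	0.9
G09	0.2	0.55	0.8
G10	0.05	0.9	0.95
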