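NR_PATHWAY	toy nuclear receptor pathway	G01	G02	G03	G04
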