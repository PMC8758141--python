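MIR-A	G01
MIR-A	G02
MIR-A	G05
MIR-B	G01
MIR-B	G05
MIR-B	G06
MIR-B	G07
MIR-C	G05
MIR-C	G06
MIR-C	G07
MIR-C	G08
MIR-C	G09
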