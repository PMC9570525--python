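gene_A	gene_B
CD274	VSIR
CD28	CD86
CD27	PDCD1
CD40	CD28
CD40	CD80
CD40	CD274
CD40	PDCD1
CD86	TNFSF4
CD86	CD200
CTLA4	TNFSF4
PDCD1	TNFSF4
CD80	TNFSF9
CD28	CD276
TNFRSF14	CD86
HAVCR2	TNFSF4
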