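StromalSignature	stromal compartment signature	PECAM1	CDH5	VWF	CLDN5	FLT1	GFAP	AQP4	S100B	SLC1A2	PDGFRB	RGS5	ACTA2	NOTCH3	COL1A1	COL1A2	COL3A1	FN1	THY1	DCN	LUM
ImmuneSignature	immune compartment signature	PTPRC	CD3E	CD3D	CD8A	CD4	AIF1	CSF1R	ITGAM	CX3CR1	TREM2	C1QA	C1QB	FCGR3A	CD14	MRC1	MSR1	CD163	IL10	TGFB1	LYZ
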