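Endothelial cells_panel_1	vascular endothelium markers	PECAM1	CDH5	VWF	CLDN5	FLT1	KDR	TEK	ESAM	TIE1	ERG	SOX17	EGFL7	ROBO4	CD34	ENG
Endothelial cells_panel_2	vascular endothelium markers (short)	PECAM1	CDH5	VWF	CLDN5	KDR
Astrocytes_panel_1	astrocyte markers	GFAP	AQP4	S100B	SLC1A2	SLC1A3	ALDH1L1	GJA1	SOX9	FGFR3	AGT	MLC1	GLUL	ATP1B2	CLU
Astrocytes_panel_2	astrocyte markers (short)	GFAP	AQP4	S100B	SLC1A3
Pericytes_panel_1	mural cell / pericyte markers	PDGFRB	RGS5	ACTA2	ANPEP	KCNJ8	CSPG4	DES	NOTCH3	MCAM	ABCC9	CD248	HIGD1B	PDGFA
Microglia_panel_1	microglia markers	AIF1	TMEM119	P2RY12	CX3CR1	ITGAM	CSF1R	TREM2	GPR34	OLFML3	SALL1	HEXB	C1QA
Neurons_panel_1	pan-neuronal markers	RBFOX3	SYT1	SNAP25	MAP2	NEFL	TUBB3	GAP43	SYN1	STMN2	DCX	ELAVL3	NRGN
Oligodendrocytes_panel_1	oligodendrocyte markers	MBP	MOG	PLP1	MAG	CNP	OLIG1	OLIG2	SOX10	CLDN11	GALC	MOBP	UGT8
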