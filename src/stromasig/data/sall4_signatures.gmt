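SALL4_CORRELATED_24	24 genes positively correlated with SALL4 across three PDAC cohorts	ANTXR1	CASC15	COL11A1	COL1A1	COL5A2	COL8A1	DCBLD1	DLG4	ITGA11	KANK4	LRRC15	MEIS3	MMP11	MMP14	NOTCH3	NOX4	NUAK1	PPEF1	PPFIBP1	PTK7	SERPINH1	SOX11	SPOCD1	UNC5B
SALL4_INVASIVE_7	SALL4-correlated genes also up-regulated in PDAC vs PanIN and vs normal pancreas	COL11A1	COL1A1	COL5A2	MMP11	NUAK1	PTK7	SERPINH1
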