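nk_receptor,alias,signal_class,ligand_genes,reported_expression_level
ILT2,"CD85j, LIR-1",inhibiting,HLA-A;HLA-B;HLA-C,High
KIR2DL2,"CD158b1, NKAT-6",inhibiting,HLA-A;HLA-C,High
KIR2DL3,"CD158b2, NKAT-2",inhibiting,HLA-C,High
NKG2A/B/KLRD1,CD159a/CD94,inhibiting,HLA-E,High
KLRG1,"CLEC15A, 2F1, MAFA",inhibiting,CDH1;CDH2;CDH4,Moderate to high
TIGIT,,inhibiting,PVR,Very low
LLT1,CLEC2D,inhibiting,KLRB1,None
FasL,"CD178, FASLG",inhibiting,FAS,Moderate
TRAIL,"CD253, TNFSF10",inhibiting,TNFRSF10A;TNFRSF10B,Moderate to high
TWEAK,TNFSF12,inhibiting,TNFRSF25,Very low
TNF-alpha,"TNF, TNFSF2",inhibiting,TNFRSF1A;TNFRSF1B,Low to moderate
NKG2E,KLRC3,activating,HLA-E,High
LFA-2,"CD2, SRBC",activating,CD58,High
NKp30,"CD337, LY117, NCR3",activating,BAG6;NCR3LG1;LGALS3,Moderate to high
NKG2D,"CD314, KLRK1",activating,MICA;MICB;ULBP1;ULBP2;ULBP3,Moderate
LFA-1,CD11a (aLb2 integrin),activating,ICAM1;ICAM2;ICAM3,Low to moderate
NKp46,"CD335, LY94, NCR1",activating,CFP;HSPG2,Very low
VLA-4 alpha chain,CD49d (a4 integrin),activating,VCAM1,Very low
ICAM1,CD54,activating,ITGAM;ITGAL,Very low
TACTILE,CD96,activating,PVR,Very low
2B4,"CD244, SLAMF4, NAIL",activating,CD48,None
KIR2DL4,"CD158d, G9P",both,HLA-G,Very low
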