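# Curated nine-pathway gene membership, restricted to genes commonly on
# breast-cancer sequencing panels.  Replaceable: pass your own
# (pathway, gene) TSV to load_catalog.
pathway	gene
cell_cycle	CDKN2A
cell_cycle	CDKN2B
cell_cycle	CDKN1A
cell_cycle	CDKN1B
cell_cycle	CCND1
cell_cycle	CCND2
cell_cycle	CCND3
cell_cycle	CCNE1
cell_cycle	CDK4
cell_cycle	CDK6
cell_cycle	RB1
cell_cycle	E2F1
cell_cycle	E2F3
Hippo	NF2
Hippo	LATS1
Hippo	LATS2
Hippo	SAV1
Hippo	STK3
Hippo	STK4
Hippo	YAP1
Hippo	WWTR1
Hippo	TAOK1
Hippo	TAOK2
Hippo	FAT1
Notch	NOTCH1
Notch	NOTCH2
Notch	NOTCH3
Notch	NOTCH4
Notch	FBXW7
Notch	SPEN
Notch	CREBBP
Notch	EP300
Notch	NCOR1
Notch	NCOR2
Notch	KDM5A
PI3K	PIK3CA
PI3K	PIK3CB
PI3K	PIK3R1
PI3K	PIK3R2
PI3K	PTEN
PI3K	AKT1
PI3K	AKT2
PI3K	AKT3
PI3K	MTOR
PI3K	TSC1
PI3K	TSC2
PI3K	STK11
PI3K	RICTOR
PI3K	RPTOR
PI3K	INPP4B
Wnt	APC
Wnt	CTNNB1
Wnt	AXIN1
Wnt	AXIN2
Wnt	TCF7L2
Wnt	AMER1
Wnt	RNF43
Wnt	ZNRF3
Wnt	GSK3B
RTK_RAS	EGFR
RTK_RAS	ERBB2
RTK_RAS	ERBB3
RTK_RAS	ERBB4
RTK_RAS	FGFR1
RTK_RAS	FGFR2
RTK_RAS	FGFR3
RTK_RAS	FGFR4
RTK_RAS	KRAS
RTK_RAS	NRAS
RTK_RAS	HRAS
RTK_RAS	BRAF
RTK_RAS	RAF1
RTK_RAS	NF1
RTK_RAS	MAP2K1
RTK_RAS	MAP2K2
RTK_RAS	MET
RTK_RAS	ALK
RTK_RAS	RET
RTK_RAS	ROS1
RTK_RAS	KIT
RTK_RAS	PDGFRA
RTK_RAS	PTPN11
RTK_RAS	SOS1
RTK_RAS	CBL
p53	TP53
p53	MDM2
p53	MDM4
p53	ATM
p53	CHEK2
p53	RPS6KA3
TGF_beta	TGFBR1
TGF_beta	TGFBR2
TGF_beta	SMAD2
TGF_beta	SMAD3
TGF_beta	SMAD4
TGF_beta	ACVR1B
TGF_beta	ACVR2A
Myc	MYC
Myc	MYCN
Myc	MYCL
Myc	MAX
Myc	MXD1
Myc	MNT
Myc	MGA
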