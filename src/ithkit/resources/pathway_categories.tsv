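# Gene -> pathway category membership for the 17 broad functional groups
# used by the category-level association models. Editable; one gene per
# line, at most one category per gene.
gene	category
SETD2	epigenetic modifiers
DNMT1	epigenetic modifiers
DNMT3A	epigenetic modifiers
DNMT3B	epigenetic modifiers
TET2	epigenetic modifiers
KMT2C	epigenetic modifiers
KMT2D	epigenetic modifiers
KDM5C	epigenetic modifiers
KDM6A	epigenetic modifiers
ARID1A	epigenetic modifiers
PBRM1	epigenetic modifiers
BAP1	epigenetic modifiers
SMARCA4	epigenetic modifiers
EP300	epigenetic modifiers
CREBBP	epigenetic modifiers
NSD1	epigenetic modifiers
EZH2	epigenetic modifiers
ASXL1	epigenetic modifiers
GATA3	transcription factors/regulators
RUNX1	transcription factors/regulators
FOXA1	transcription factors/regulators
FOXA2	transcription factors/regulators
CTCF	transcription factors/regulators
TBX3	transcription factors/regulators
SOX9	transcription factors/regulators
VEZF1	transcription factors/regulators
EIF4A2	transcription factors/regulators
TAF1	transcription factors/regulators
TP53	genome integrity
ATM	genome integrity
ATR	genome integrity
ATRX	genome integrity
BRCA1	genome integrity
BRCA2	genome integrity
CHEK2	genome integrity
STAG2	genome integrity
SMC1A	genome integrity
SMC3	genome integrity
ERCC2	genome integrity
EGFR	RTK signaling
ERBB2	RTK signaling
ERBB4	RTK signaling
FGFR2	RTK signaling
FGFR3	RTK signaling
PDGFRA	RTK signaling
KIT	RTK signaling
MET	RTK signaling
FLT3	RTK signaling
RB1	cell cycle
CDKN2A	cell cycle
CDKN1B	cell cycle
CDK4	cell cycle
CCND1	cell cycle
CDC27	cell cycle
KRAS	MAPK signaling
NRAS	MAPK signaling
HRAS	MAPK signaling
BRAF	MAPK signaling
MAP2K1	MAPK signaling
MAP3K1	MAPK signaling
NF1	MAPK signaling
PIK3CA	PI(3)K signaling
PIK3R1	PI(3)K signaling
PIK3CG	PI(3)K signaling
PTEN	PI(3)K signaling
AKT1	PI(3)K signaling
TSC1	PI(3)K signaling
TSC2	PI(3)K signaling
INPP4B	PI(3)K signaling
SMAD2	TGF-beta signaling
SMAD4	TGF-beta signaling
TGFBR2	TGF-beta signaling
ACVR1B	TGF-beta signaling
ACVR2A	TGF-beta signaling
APC	Wnt/beta-catenin signaling
CTNNB1	Wnt/beta-catenin signaling
AXIN1	Wnt/beta-catenin signaling
AXIN2	Wnt/beta-catenin signaling
TCF7L2	Wnt/beta-catenin signaling
DKK1	Wnt/beta-catenin signaling
VHL	proteolysis
KEAP1	proteolysis
SPOP	proteolysis
FBXW7	proteolysis
SF3B1	splicing
U2AF1	splicing
SRSF2	splicing
ZRSR2	splicing
PCBP1	splicing
NF2	HIPPO signaling
LATS1	HIPPO signaling
LATS2	HIPPO signaling
FAT1	HIPPO signaling
CDH1	HIPPO signaling
IDH1	metabolism
IDH2	metabolism
SDHB	metabolism
FH	metabolism
NFE2L2	NFE2L
NFE2L3	NFE2L
PPP2R1A	protein phosphatase
PPP6C	protein phosphatase
PTPN11	protein phosphatase
RPL5	ribosome
RPL22	ribosome
RPL10	ribosome
MTOR	TOR
STK11	TOR
RICTOR	TOR
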