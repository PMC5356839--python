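Name	CodeClass	Accession
ACSL1	Endogenous	NA
ADAMTS8	Endogenous	NA
ADCY4	Endogenous	NA
ASS1	Endogenous	NA
AURKA	Endogenous	NA
BAP1	Endogenous	NA
BIRC5	Endogenous	NA
BMP1	Endogenous	NA
BUB1	Endogenous	NA
CAV1	Endogenous	NA
CCNB1	Endogenous	NA
CCNB2	Endogenous	NA
CCNO	Endogenous	NA
CD274	Endogenous	NA
CD44	Endogenous	NA
CDH1	Endogenous	NA
CDH11	Endogenous	NA
CDK1	Endogenous	NA
CDK4	Endogenous	NA
CDK7	Endogenous	NA
CDKN2A	Endogenous	NA
CDKN2B	Endogenous	NA
CENPF	Endogenous	NA
CFB	Endogenous	NA
CHEK1	Endogenous	NA
CLDN15	Endogenous	NA
COL16A1	Endogenous	NA
COL1A1	Endogenous	NA
COL4A2	Endogenous	NA
CTNNA1	Endogenous	NA
CXADR	Endogenous	NA
DNMT1	Endogenous	NA
DNMT3A	Endogenous	NA
DSP	Endogenous	NA
EEF2	Endogenous	NA
EGFR	Endogenous	NA
EGR3	Endogenous	NA
EIF4G1	Endogenous	NA
EMX2	Endogenous	NA
ESR2	Endogenous	NA
FANCI	Endogenous	NA
FGF2	Endogenous	NA
FN1	Endogenous	NA
GALNT7	Endogenous	NA
GLI1	Endogenous	NA
GLI2	Endogenous	NA
GNAQ	Endogenous	NA
HEG1	Endogenous	NA
IFITM1	Endogenous	NA
ITGA3	Endogenous	NA
ITGA4	Endogenous	NA
ITGA5	Endogenous	NA
ITGA7	Endogenous	NA
ITGAM	Endogenous	NA
ITGB4	Endogenous	NA
JAG1	Endogenous	NA
JUNB	Endogenous	NA
KRT5	Endogenous	NA
LAMA3	Endogenous	NA
LAMC1	Endogenous	NA
LGALS3	Endogenous	NA
LGALS3BP	Endogenous	NA
MAD2L1	Endogenous	NA
MAGED1	Endogenous	NA
MCM2	Endogenous	NA
MCM4	Endogenous	NA
MICAL2	Endogenous	NA
MKI67	Endogenous	NA
MMP1	Endogenous	NA
MMP10	Endogenous	NA
MMP12	Endogenous	NA
MMP14	Endogenous	NA
MMP3	Endogenous	NA
MMP7	Endogenous	NA
MMP9	Endogenous	NA
MSLN	Endogenous	NA
MYH11	Endogenous	NA
NDC80	Endogenous	NA
NF2	Endogenous	NA
NME2	Endogenous	NA
NMU	Endogenous	NA
NOTCH1	Endogenous	NA
PAK4	Endogenous	NA
PAPPA	Endogenous	NA
PCNA	Endogenous	NA
PDCD1	Endogenous	NA
PDGFRB	Endogenous	NA
PECAM1	Endogenous	NA
PIK3CA	Endogenous	NA
PKM	Endogenous	NA
PLK1	Endogenous	NA
PLK2	Endogenous	NA
PPARA	Endogenous	NA
PTGIS	Endogenous	NA
PTGS2	Endogenous	NA
RAD21	Endogenous	NA
SDC1	Endogenous	NA
SDHB	Endogenous	NA
SELE	Endogenous	NA
SERPINE1	Endogenous	NA
SFRP1	Endogenous	NA
SMARCA4	Endogenous	NA
SOD1	Endogenous	NA
SULF1	Endogenous	NA
TACC1	Endogenous	NA
TERT	Endogenous	NA
TGFBR2	Endogenous	NA
THBS2	Endogenous	NA
TIMP3	Endogenous	NA
TNPO2	Endogenous	NA
TOP2A	Endogenous	NA
TPPP	Endogenous	NA
TUBB2B	Endogenous	NA
UBE2T	Endogenous	NA
VEGFA	Endogenous	NA
VWF	Endogenous	NA
XPOT	Endogenous	NA
CLTC	Housekeeping	NA
GAPDH	Housekeeping	NA
GUSB	Housekeeping	NA
HPRT1	Housekeeping	NA
PGK1	Housekeeping	NA
TUBB	Housekeeping	NA
POS_A(128)	Positive	ERCC_00000
POS_B(32)	Positive	ERCC_00000
POS_C(8)	Positive	ERCC_00000
POS_D(2)	Positive	ERCC_00000
POS_E(0.5)	Positive	ERCC_00000
POS_F(0.125)	Positive	ERCC_00000
NEG_A(0)	Negative	ERCC_00000
NEG_B(0)	Negative	ERCC_00000
NEG_C(0)	Negative	ERCC_00000
NEG_D(0)	Negative	ERCC_00000
NEG_E(0)	Negative	ERCC_00000
NEG_F(0)	Negative	ERCC_00000
NEG_G(0)	Negative	ERCC_00000
NEG_H(0)	Negative	ERCC_00000
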