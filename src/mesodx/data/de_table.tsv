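gene	z	p	direction
ITGB4	-4.70564	0.000003	up_in_MPM
ITGA3	-4.67538	0.000003	up_in_MPM
MCM4	-4.52408	0.000006	up_in_MPM
KRT5	-4.46355	0.000008	up_in_MPM
NMU	-4.31461	0.000016	up_in_MPM
FANCI	-4.22146	0.000024	up_in_MPM
CCNB1	-4.07016	0.000047	up_in_MPM
DSP	-3.70702	0.000210	up_in_MPM
RAD21	-3.64650	0.000266	up_in_MPM
CENPF	-3.58597	0.000336	up_in_MPM
TOP2A	-3.55571	0.000377	up_in_MPM
MCM2	-3.52545	0.000423	up_in_MPM
PAK4	-3.52545	0.000423	up_in_MPM
EGFR	-3.40440	0.000663	up_in_MPM
MSLN	-3.40440	0.000663	up_in_MPM
CCNB2	-3.34388	0.000826	up_in_MPM
CLDN15	-3.28336	0.001026	up_in_MPM
CCNO	-3.25551	0.001132	up_in_MPM
BIRC5	-3.25328	0.001141	up_in_MPM
CDK7	-3.16231	0.001565	up_in_MPM
CDH1	-3.13222	0.001735	up_in_MPM
NME2	-3.07153	0.002130	up_in_MPM
LGALS3BP	-2.98075	0.002876	up_in_MPM
PKM	-2.92022	0.003498	up_in_MPM
MKI67	-2.85970	0.004241	up_in_MPM
BUB1	-2.79918	0.005124	up_in_MPM
PLK1	-2.58735	0.009672	up_in_MPM
CDK1	-2.55709	0.010556	up_in_MPM
CXADR	-2.52682	0.011510	up_in_MPM
AURKA	-2.49656	0.012541	up_in_MPM
UBE2T	-2.43604	0.014850	up_in_MPM
Gli2	-2.40578	0.016139	up_in_MPM
LAMA3	-2.31500	0.020614	up_in_MPM
CHEK1	-2.13343	0.032890	up_in_MPM
NDC80	-2.13343	0.032890	up_in_MPM
MICAL2	-1.95186	0.050956	up_in_MPM
MMP3	-1.93918	0.052480	up_in_MPM
SMARCA4	-1.92160	0.054657	up_in_MPM
ASS1	-1.89134	0.058580	up_in_MPM
GALNT7	-1.83081	0.067129	up_in_MPM
MAGED1	-1.83081	0.067129	up_in_MPM
PCNA	-1.83081	0.067129	up_in_MPM
EIF4G1	-1.77029	0.076680	up_in_MPM
CDH11	-1.67951	0.093054	up_in_MPM
MAD2L1	-1.37689	0.168546	up_in_MPM
HEG1	-1.01376	0.310700	up_in_MPM
ADAMTS8	-0.91104	0.362276	up_in_MPM
PLK2	-0.83219	0.405304	up_in_MPM
VEGFA	-0.71114	0.476997	up_in_MPM
CTNNA1	-0.62036	0.535022	up_in_MPM
CFB	-0.59010	0.555126	up_in_MPM
TIMP3	-0.52957	0.596408	up_in_MPM
TNPO2	-0.43879	0.660814	up_in_MPM
IFITM1	-0.40853	0.682886	up_in_MPM
MMP10	-0.28336	0.776901	up_in_MPM
DNMT3A	-0.25722	0.797008	up_in_MPM
XPOT	-0.25722	0.797008	up_in_MPM
SULF1	-0.13618	0.891682	up_in_MPM
LGALS3	4.79643	0.000002	down_in_MPM
PDGFRB	4.61486	0.000004	down_in_MPM
ITGAM	4.37277	0.000012	down_in_MPM
PECAM1	4.25172	0.000021	down_in_MPM
CAV1	4.16094	0.000032	down_in_MPM
MMP9	3.97959	0.000069	down_in_MPM
NF2	3.82806	0.000129	down_in_MPM
PAPPA	3.70702	0.000210	down_in_MPM
ITGA5	3.67676	0.000236	down_in_MPM
TACC1	3.67676	0.000236	down_in_MPM
MYH11	3.49538	0.000473	down_in_MPM
CD44	3.40440	0.000663	down_in_MPM
PPARA	3.28336	0.001026	down_in_MPM
ACSL1	3.13205	0.001736	down_in_MPM
TGFBR2	3.10179	0.001924	down_in_MPM
BAP1	3.07153	0.002130	down_in_MPM
VWF	3.04143	0.002355	down_in_MPM
MMP1	3.02832	0.002459	down_in_MPM
FN1	2.70839	0.006761	down_in_MPM
ITGA7	2.70839	0.006761	down_in_MPM
ADCY4	2.67813	0.007404	down_in_MPM
MMP7	2.62642	0.008629	down_in_MPM
COL1A1	2.58735	0.009672	down_in_MPM
NOTCH1	2.52682	0.011510	down_in_MPM
TPPP	2.49930	0.012444	down_in_MPM
JAG1	2.37552	0.017525	down_in_MPM
DNMT1	2.13343	0.032890	down_in_MPM
EGR3	2.13343	0.032890	down_in_MPM
EMX2	2.04893	0.040470	down_in_MPM
Gli1	2.03705	0.041646	down_in_MPM
SOD1	2.01238	0.044181	down_in_MPM
PTGS2	1.89134	0.058580	down_in_MPM
ESR2	1.81249	0.069911	down_in_MPM
SELE	1.78203	0.074745	down_in_MPM
JUNB	1.52820	0.126464	down_in_MPM
COL16A1	1.37689	0.168546	down_in_MPM
PTGIS	1.31637	0.188051	down_in_MPM
SDHB	1.31637	0.188051	down_in_MPM
EEF2	1.28611	0.198406	down_in_MPM
COL4A2	1.16506	0.243994	down_in_MPM
ITGA4	1.16506	0.243994	down_in_MPM
PIK3CA	1.13480	0.256459	down_in_MPM
MMP12	1.04605	0.295541	down_in_MPM
SDC1	1.01376	0.310700	down_in_MPM
BMP1	0.98349	0.325365	down_in_MPM
TUBB2B	0.89276	0.371987	down_in_MPM
TERT	0.82029	0.412050	down_in_MPM
CD274	0.77167	0.440313	down_in_MPM
CDK4	0.77167	0.440313	down_in_MPM
MMP14	0.77167	0.440313	down_in_MPM
GNAQ	0.74140	0.458449	down_in_MPM
THBS2	0.71114	0.476997	down_in_MPM
PDCD1	0.68092	0.495924	down_in_MPM
CDKN2B	0.65062	0.515293	down_in_MPM
SERPINE1	0.46905	0.639033	down_in_MPM
SFRP1	0.37827	0.705232	down_in_MPM
FGF2	0.28748	0.773743	down_in_MPM
LAMC1	0.25722	0.797008	down_in_MPM
CDKN2A	0.09096	0.927526	down_in_MPM
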