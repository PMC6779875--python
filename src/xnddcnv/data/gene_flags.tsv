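gene_id	symbol	pli	brain_expressed	is_ndd	is_gig	is_lncrna
SKI	SKI	0.96	1	1	0	0
HFE2	HFE2	0.00	0	1	0	0
PSMD4	PSMD4	0.62	1	0	0	0
POGZ	POGZ	1.00	1	1	0	0
DISC1	DISC1	0.01	1	1	0	0
EXO1	EXO1	0.00	0	0	1	0
ZFAND4	ZFAND4	0.02	0	0	0	0
MARCH8	MARCH8	0.25	1	0	0	0
CHAT	CHAT	0.00	1	0	0	0
PCDH15	PCDH15	0.00	1	1	0	0
CTNNA3	CTNNA3	0.00	1	1	0	0
BTRC	BTRC	0.99	1	0	0	0
POLL	POLL	0.01	0	1	0	0
DPCD	DPCD	0.00	0	0	0	0
DRD4	DRD4	0.01	1	1	0	0
ELP4	ELP4	0.26	1	0	0	0
PAX6	PAX6	1.00	1	1	0	0
SHANK2	SHANK2	1.00	1	1	0	0
DLG2	DLG2	0.99	1	1	0	0
CNTN5	CNTN5	0.21	1	1	0	0
KMT2A	KMT2A	1.00	1	1	0	0
CACNA1C	CACNA1C	1.00	1	1	0	0
PCDH9	PCDH9	0.93	1	1	0	0
CHD8	CHD8	1.00	1	1	0	0
NRXN3	NRXN3	0.98	1	1	0	0
APBA2	APBA2	0.89	1	1	0	0
CHRNA7	CHRNA7	0.47	1	1	0	0
RBFOX1	RBFOX1	0.99	1	1	0	0
USP7	USP7	1.00	1	0	0	0
NDE1	NDE1	0.25	1	0	0	0
PALB2	PALB2	0.00	0	0	1	0
ATP2A1	ATP2A1	0.02	1	1	0	0
SALL1	SALL1	0.99	1	0	0	0
ATP2C2	ATP2C2	0.00	1	1	0	0
TLDC1	TLDC1	0.10	1	0	0	0
ANKRD11	ANKRD11	1.00	1	1	0	0
INPP5K	INPP5K	0.02	1	0	0	0
PITPNA	PITPNA	0.91	1	0	0	0
NF1	NF1	1.00	1	1	0	0
ACTG1	ACTG1	0.89	1	0	0	0
CSNK1D	CSNK1D	0.99	1	0	0	0
COLEC12	COLEC12	0.00	0	0	0	0
YES1	YES1	0.76	1	0	0	0
DLGAP1	DLGAP1	0.97	1	1	0	0
CDH7	CDH7	0.03	1	1	0	0
CDH19	CDH19	0.01	1	0	0	0
GRIN2D	GRIN2D	0.82	1	0	0	0
NRXN1	NRXN1	0.99	1	1	0	0
DPP10	DPP10	0.86	1	1	0	0
CNTNAP5	CNTNAP5	0.00	1	1	0	0
MBD5	MBD5	0.97	1	1	0	0
NR4A2	NR4A2	0.91	1	0	0	0
GPD2	GPD2	0.01	1	0	0	0
GULP1	GULP1	0.12	1	0	0	0
MACROD2	MACROD2	0.01	1	1	0	0
PTPRT	PTPRT	0.99	1	1	0	0
PDE9A	PDE9A	0.00	1	0	0	0
TBX1	TBX1	0.33	1	0	0	0
SNAP29	SNAP29	0.26	1	1	0	0
LZTR1	LZTR1	0.97	1	0	0	0
UPB1	UPB1	0.00	0	0	0	0
CACNA1I	CACNA1I	0.99	1	1	0	0
CNTN6	CNTN6	0.03	1	1	0	0
CNTN4	CNTN4	0.74	1	1	0	0
SUMF1	SUMF1	0.01	1	1	0	0
ITPR1	ITPR1	1.00	1	1	0	0
GRM7	GRM7	0.99	1	1	0	0
FAM19A1	FAM19A1	0.37	1	0	0	0
MBD4	MBD4	0.00	0	0	1	0
NLGN1	NLGN1	0.98	1	1	0	0
PAK2	PAK2	1.00	1	1	0	0
DLG1	DLG1	1.00	1	1	0	0
BDH1	BDH1	0.00	1	0	0	0
ADRA2C	ADRA2C	0.30	1	0	0	0
COX18	COX18	0.00	0	0	0	0
ANKRD17	ANKRD17	1.00	1	1	0	0
GRID2	GRID2	0.92	1	1	0	0
PITX2	PITX2	0.90	1	0	0	0
ANK2	ANK2	1.00	1	1	0	0
CTNND2	CTNND2	1.00	1	1	0	0
RAD1	RAD1	0.01	0	0	1	0
TMEM161B	TMEM161B	0.26	1	0	0	0
MEF2C	MEF2C	1.00	1	1	0	0
PTPRK	PTPRK	0.98	1	1	0	0
LAMA2	LAMA2	0.00	1	1	0	0
ARHGAP18	ARHGAP18	0.18	1	0	0	0
FOXK1	FOXK1	0.95	1	0	0	0
AP5Z1	AP5Z1	0.00	1	0	0	0
TNRC18	TNRC18	0.99	1	0	0	0
FBXL18	FBXL18	0.57	1	0	0	0
AUTS2	AUTS2	0.99	1	1	0	0
ELN	ELN	0.21	1	1	0	0
FOXP2	FOXP2	1.00	1	1	0	0
GRM8	GRM8	0.96	1	1	0	0
CNTNAP2	CNTNAP2	0.99	1	1	0	0
KMT2C	KMT2C	1.00	1	1	0	0
DPP6	DPP6	0.99	1	1	0	0
PAXIP1	PAXIP1	0.98	1	0	0	0
HTR5A	HTR5A	0.51	1	0	0	0
EN2	EN2	0.71	1	0	0	0
RBM33	RBM33	0.88	1	0	0	0
CNPY1	CNPY1	0.05	1	0	0	0
PTPRN2	PTPRN2	0.83	1	1	0	0
ESYT2	ESYT2	0.13	1	0	0	0
NCAPG2	NCAPG2	0.00	1	0	0	0
DLGAP2	DLGAP2	0.95	1	1	0	0
CLN8	CLN8	0.02	1	0	0	0
ARHGEF10	ARHGEF10	0.00	1	0	0	0
MCPH1	MCPH1	0.00	1	1	0	0
PTPRD	PTPRD	1.00	1	1	0	0
PAPPA	PAPPA	0.27	1	0	0	0
ASTN2	ASTN2	0.95	1	1	0	0
TRIM32	TRIM32	0.01	1	0	0	0
ARSE	ARSE	0.04	0	1	0	0
VCX3B	VCX3B	0.00	0	0	0	0
ANOS1	ANOS1	0.93	1	1	0	0
PTCHD1-AS	PTCHD1-AS		1	1	0	1
IL1RAPL1	IL1RAPL1	0.96	1	1	0	0
TAB3	TAB3	0.90	1	0	0	0
FTHL17	FTHL17	0.00	0	0	0	0
DMD	DMD	0.91	1	1	0	0
SMC1A	SMC1A	1.00	1	1	0	0
RAB38B	RAB38B	0.55	1	1	0	0
SRY	SRY	0.00	0	0	0	0
RBMY1A1	RBMY1A1	0.00	0	0	0	0
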