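gene_id	chrom	arm	n_probes
MTOR	1	p	23
ID3	1	p	23
ARID1A	1	p	23
CSF3R	1	p	23
MPL	1	p	23
JAK1	1	p	23
NRAS	1	p	22
MYCL	1	p	22
SDHB	1	p	22
FASLG	1	q	22
MDM4	1	q	22
H3F3A	1	q	22
ABL2	1	q	22
MYCN	2	p	22
ALK	2	p	22
DNMT3A	2	p	22
ASXL2	2	p	22
IDH1	2	q	22
ERBB4	2	q	22
SETD2	3	p	22
RHOA	3	p	22
CCR5	3	p	22
MLH1	3	p	22
CTNNB1	3	p	22
PIK3CA	3	q	22
MECOM	3	q	22
FBXW7	4	q	22
PDGFRA	4	q	22
KIT	4	q	22
TERT	5	p	22
IL7R	5	p	22
APC	5	q	22
CSF1R	5	q	22
EBF1	5	q	22
FGFR4	5	q	22
MYB	6	q	22
ROS1	6	q	22
ARID1B	6	q	22
EGFR	7	p	22
CARD11	7	p	22
PMS2	7	p	22
CDK6	7	q	22
MET	7	q	22
BRAF	7	q	22
SMO	7	q	22
EZH2	7	q	22
FGFR1	8	p	22
IKBKB	8	p	22
MYC	8	q	22
RAD21	8	q	22
CDKN2A	9	p	22
KDM4C	9	p	22
JAK2	9	p	22
ABL1	9	q	22
NOTCH1	9	q	22
TSC1	9	q	22
PTEN	10	q	22
FGFR2	10	q	22
WT1	11	p	22
HRAS	11	p	22
LMO2	11	p	22
CBL	11	q	22
EED	11	q	22
ATM	11	q	22
KMT2A	11	q	22
SDHD	11	q	22
BIRC3	11	q	22
POU2AF1	11	q	22
KRAS	12	p	22
ETV6	12	p	22
CCND2	12	p	22
MDM2	12	q	22
CDK4	12	q	22
PTPN11	12	q	22
RB1	13	q	22
FLT3	13	q	22
BRCA2	13	q	22
FOXO1	13	q	22
AKT1	14	q	22
TRAF3	14	q	22
DICER1	14	q	22
MAX	14	q	22
IDH2	15	q	22
NTRK3	15	q	22
MAP2K1	15	q	22
CREBBP	16	p	22
AXIN1	16	p	22
TSC2	16	p	22
CTCF	16	q	22
CDH1	16	q	22
TP53	17	p	22
MAP2K4	17	p	22
NCOR1	17	p	22
GNA13	17	q	22
PPM1D	17	q	22
STAT3	17	q	22
STAT5B	17	q	22
BRCA1	17	q	22
ERBB2	17	q	22
NF1	17	q	22
SUZ12	17	q	22
CDK12	17	q	22
RPS6KB1	17	q	22
AXIN2	17	q	22
SPOP	17	q	22
TOP2A	17	q	22
RARA	17	q	22
SMAD4	18	q	22
SETBP1	18	q	22
BCL2	18	q	22
STK11	19	p	22
KEAP1	19	p	22
SMARCA4	19	p	22
GNA11	19	p	22
MAP2K2	19	p	22
JAK3	19	p	22
AKT2	19	q	22
CIC	19	q	22
AURKA	20	q	22
GNAS	20	q	22
SRC	20	q	22
ASXL1	20	q	22
RUNX1	21	q	22
ERG	21	q	22
NF2	22	q	22
SMARCB1	22	q	22
EP300	22	q	22
CHEK2	22	q	22
GATA1	X	p	22
KDM6A	X	p	22
BCOR	X	p	22
ATRX	X	q	22
XIAP	X	q	22
SH2D1A	X	q	22
STAG2	X	q	22
PHF6	X	q	22
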