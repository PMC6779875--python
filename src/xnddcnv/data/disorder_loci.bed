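# Recurrent genomic-disorder critical regions, GRCh37 (DECIPHER/ClinGen-style
# coordinates, rounded). Columns: chrom start end name score strand expected_type.
# Where a syndrome presents both a short canonical region and a longer
# LCR-extended form (16p13.11), both are listed; locus matching takes the
# entry with the highest reciprocal overlap.
1	145386000	145748000	1q21.1_TAR_deletion	0	.	DEL
1	145386000	147826000	1q21.1_distal_duplication	0	.	DUP
2	239716000	243199373	2q37.3_deletion	0	.	DEL
3	195720000	197354000	3q29_deletion	0	.	DEL
4	700000	1900000	4p16.3_duplication	0	.	DUP
5	100000	12200000	5p_cri_du_chat_deletion	0	.	DEL
7	72744000	74142000	7q11.23_WBS_deletion	0	.	DEL
7	72744000	74142000	7q11.23_duplication	0	.	DUP
9	139000000	141150000	9q34.3_duplication	0	.	DUP
10	49390000	51060000	10q11.22q11.23_duplication	0	.	DUP
15	22765000	28390000	15q11q13_duplication	0	.	DUP
15	22765000	23217000	15q11.2_BP1BP2_deletion	0	.	DEL
15	22765000	23217000	15q11.2_BP1BP2_duplication	0	.	DUP
15	30910000	32445000	15q13.3_deletion	0	.	DEL
15	84700000	85700000	15q25_distal_deletion	0	.	DEL
16	3775000	3930000	16p13.3_RTS_duplication	0	.	DUP
16	15490000	16300000	16p13.11_deletion	0	.	DEL
16	15000000	18200000	16p13.11_p12.3_deletion	0	.	DEL
16	15490000	16300000	16p13.11_duplication	0	.	DUP
16	15000000	18200000	16p13.11_p12.3_duplication	0	.	DUP
16	21950000	22650000	16p12.1_duplication	0	.	DUP
16	21950000	22650000	16p12.1_deletion	0	.	DEL
16	28820000	29050000	16p11.2_distal_duplication	0	.	DUP
16	28820000	29050000	16p11.2_distal_deletion	0	.	DEL
16	29650000	30200000	16p11.2_proximal_duplication	0	.	DUP
16	29650000	30200000	16p11.2_proximal_deletion	0	.	DEL
17	14100000	15430000	17p12_HNPP_deletion	0	.	DEL
17	34815000	36217000	17q12_duplication	0	.	DUP
22	18890000	21460000	22q11.21_deletion	0	.	DEL
22	18890000	21460000	22q11.21_duplication	0	.	DUP
22	23650000	25700000	22q11.2_distal_duplication	0	.	DUP
22	51000000	51304566	22q13.33_deletion	0	.	DEL
X	6455000	8135000	Xp22.3_STS_deletion	0	.	DEL
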