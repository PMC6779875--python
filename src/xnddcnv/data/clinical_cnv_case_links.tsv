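# Cases carrying more than one clinically relevant CNV: 12 ASD, 3 ADHD,
# 3 OCD and 1 SCZ multi-CNV cases plus one ASD case holding both CNVs of row
# D19, reconstructed from the cohort narrative and the per-disorder CNV/case
# totals (223/43/17/23 CNVs in 209/40/13/22 unique cases). Named case ids are
# the source's; pair-N ids are reconstructed pairs whose identities were not
# narrated. Members select one not-yet-linked subject of the named row,
# optionally filtered by disorder/origin/sex; set_sex= forces the case sex.
# case_id	members
4-0040-003	E41[origin=M,sex=F];E11[];D17[]
7-0293-003	C24[disorder=ASD,origin=U,sex=M];C12[disorder=ASD,origin=U,sex=M]
2-1525-003	C17[disorder=ASD,origin=M,set_sex=F];D12[]
2-0305-004	C01[origin=M];D03[]
asd-pde9a-case	D19[];D19[]
213050	A3[disorder=ADHD];E37[disorder=ADHD]
206760	E36[disorder=ADHD];E43[]
235983S	A3[disorder=ADHD];E32[disorder=ADHD]
OCD146-JS-1254_188613	E15[];E33[disorder=OCD];E34[disorder=OCD]
OCD125-896993	D05[];E10[disorder=OCD]
OCD109-1648	C25[];E67[]
222720	C06[];B07[]
asd-pair-1	E03[];E04[]
asd-pair-2	E07[];E14[]
asd-pair-3	E50[];E51[]
asd-pair-4	E24[];E46[]
asd-pair-5	E29[];E64[]
asd-pair-6	E20[];E55[]
asd-pair-7	C04[];E47[]
asd-pair-8	C09[];E69[]
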