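# Chromosome-level CIN overview for a 21-sample high-risk GIST cohort
# (10 metastatic, 11 non-metastatic): per-sample counts of chromosomes
# affected by CNV only, copy-neutral LOH only, and both, the total,
# the Simple/Complex karyotype label, tumour ploidy and mitotic count.
sample	group	n_chr_cnv	n_chr_loh	n_chr_cnv_loh	n_chr_total	cin	ploidy	mitotic_count
GIST1	metastatic	8	0	5	13	Complex	1.82	12
GIST3	metastatic	11	1	0	12	Complex	1.82	35
GIST5	metastatic	9	3	0	12	Complex	1.91	11
GIST6	metastatic	18	0	4	22	Complex	1.17	166
GIST7	metastatic	9	1	2	12	Complex	1.81	20
GIST8	metastatic	17	1	5	23	Complex	3.27	50
GIST10	metastatic	10	1	0	11	Complex	1.83	51
GIST11	metastatic	7	0	0	7	Simple	1.87	3
GIST12	metastatic	17	0	1	18	Complex	1.72	15
GIST24	metastatic	13	0	2	15	Complex	1.86	178
GIST13	non_metastatic	7	0	0	7	Simple	1.9	11
GIST14	non_metastatic	18	0	2	20	Complex	3.47	7
GIST15	non_metastatic	3	0	0	3	Simple	1.97	1
GIST16	non_metastatic	2	0	0	2	Simple	1.95	7
GIST17	non_metastatic	7	0	0	7	Simple	1.90	130
GIST18	non_metastatic	5	0	0	5	Simple	1.97	32
GIST19	non_metastatic	9	0	3	12	Complex	2.07	13
GIST20	non_metastatic	6	0	0	6	Simple	1.85	7
GIST21	non_metastatic	1	0	0	1	Simple	1.96	7
GIST22	non_metastatic	2	0	0	2	Simple	2.02	2
GIST23	non_metastatic	6	0	0	6	Simple	1.75	1
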