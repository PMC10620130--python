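# Chromothriptic chromosomes of the high-confidence-scored samples in the
# 21-sample GIST cohort: per chromosome the number of copy-number switches
# within 50 Mb, alongside the sample's Simple/Complex karyotype label.
sample	group	chrom	switches_within_50mb	cin
GIST1	metastatic	1	9	Complex
GIST1	metastatic	3	12	Complex
GIST1	metastatic	16	14	Complex
GIST1	metastatic	21	10	Complex
GIST7	metastatic	1	26	Complex
GIST11	metastatic	8	12	Simple
GIST11	metastatic	19	6	Simple
GIST24	metastatic	7	12	Complex
GIST24	metastatic	12	10	Complex
GIST24	metastatic	17	30	Complex
GIST24	metastatic	19	11	Complex
GIST19	non_metastatic	1	31	Complex
GIST19	non_metastatic	9	8	Complex
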