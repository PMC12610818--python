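mirna	sequence	length	mismatch	mfe	ed
dro-let-7-5p	TGAGGTAGTAGGTTGTATAGTTT	23	0	-23.3	9.55
dro-miR-1271-3p	TGCCTGGCACACAGCAGGCAC	21	0	-28.6	3.82
dro-miR-1291b	GGCCCTGAATCAAGGCCAGCAGT	23	1	-21.3	3.93
dro-miR-1302	TTGGGACATACTTATACTAAA	21	0	-20.9	2.22
dro-miR-133a-5p	AGCTGGTAAAATGGAACCAAAT	22	0	-21.2	4.08
dro-miR-2309	GAGGGTGGTGGAAGGCAGGG	20	1	-27.0	4.81
dro-miR-296-5p	GAGGGCCTCCCTCAACCCTG	20	0	-30.3	14.7
dro-miR-3072	GAAGGCTTCCTGGAGGGGG	19	0	-20.4	4.17
dro-miR-3173	GGCCTGCCTGTGTCCTCCT	19	1	-34.9	2.11
dro-miR-3596	TGAGGTAGTAGGTTGTGTGGTT	22	0	-25.3	4.20
dro-miR-3620-5p	GGCCCAGCCCAGCCCAGCCC	20	0	-26.6	12.38
dro-miR-544-5p	GAATCTGCCTTTTAACAAG	19	0	-22.5	5.59
dro-miR-6732-3p	GGGAGGGGGAGGACAGGGTT	20	1	-22.4	4.58
dro-miR-6736-5p	CTGGGTGAGGGCTTCTGTGG	20	1	-20.1	5.46
dro-miR-6988-5p	GGGCCTCAGCTCACCACCC	19	1	-33.1	10.24
dro-miR-7033-5p	CCAGGGGTCTGAGGGGCA	18	1	-22.4	6.91
dro-miR-8839	TTGGCAGAGCCAGGGTTCAA	20	1	-22.0	3.36
dro-miR-9222	TAGAAGTCCAAACTCAAGGTG	21	1	-21.2	8.38
dro-miR-9993b-3p	TGGAGGCCCCAGCGAGAT	18	0	-20.5	13.67
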