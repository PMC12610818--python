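mirna	gene	coding_protein	binding_score	region	binding_energy	validated_id
dro-let-7c-5p	TUBB4A	NM_006087	1.0	3UTR	-25.7	MIRT735640
dro-let-7c-5p	ABT1	NM_013375	1.0	3UTR	-23.4	MIRT100093
dro-let-7c-5p	CHST6	NM_021615	1.0	3UTR	-24.9	MIRT051817
dro-miR-1271-3p	CPM	NM_198320	1.0	3UTR	-36.4	MIRT514569
dro-miR-1271-3p	LSM11	NM_173491	1.0	3UTR	-32.3	MIRT522699
dro-miR-1271-3p	NT5C1B	NM_033253	1.0	3UTR	-30.7	MIRT451045
dro-miR-1302	DNAL1	NM_001201366	1.0	3UTR	-20.3	MIRT688422
dro-miR-1302	SOD2	NM_001322814	1.0	3UTR	-17.9	MIRT525780
dro-miR-133a-5p	RUNX3	NM_004350	1.0	3UTR	-18.6	MIRT561635
dro-miR-133a-5p	NR3C1	NM_001364184	1.0	3UTR	-18.5	MIRT687439
dro-miR-1587	RNF4	NM_001185009	1.0	3UTR	-33.8	MIRT121369
dro-miR-1587	TRIM28	NM_005762	1.0	3UTR	-33.6	MIRT737922
dro-miR-296-5p	ELAVL3	NM_032281	1.0	3UTR	-37.6	MIRT624037
dro-miR-296-5p	FGFR1	NM_001354368	1.0	3UTR	-32.0	MIRT734669
dro-miR-3620-5p	SLC12A7	XM_047416640	1.0	3UTR	-37.1	MIRT766116
dro-miR-3620-5p	TAF8	XM_017010241	1.0	3UTR	-35.5	MIRT560359
dro-miR-6732-3p	ALKBH4	NM_017621	1.0	3UTR	-35.2	MIRT648662
dro-miR-6732-3p	TMEM9B	NM_001286094	1.0	3UTR	-31.0	MIRT446991
dro-miR-6736-5p	SPRYD4	NM_207344	1.0	3UTR	-32.2	MIRT607891
dro-miR-6736-5p	FAM83F	NM_138435	1.0	3UTR	-30.5	MIRT542970
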