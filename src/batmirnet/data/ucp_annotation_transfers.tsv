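accession	homolog_species	annotation	percent_identity	evalue
XP_045053599.2	mouse	PDZ and pleckstrin homology domains 1	57.21	0
XP_071076900.1	Rousettus aegyptiacus	neuronal-specific septin-3 isoform X1	69.84	0
XP_024421750.2	Phyllostomus discolor	nascent polypeptide-associated complex subunit alpha	79.30	0
XP_053775687.1	Rousettus aegyptiacus	orofacial cleft 1 candidate gene 1 protein	80.74	0
XP_053784895.1	Phyllostomus discolor	syncytin-1	94.25	0
XP_045054974.2	Pteropus vampyrus	PH domain-containing protein 1	76.39	8.34e-166
XP_053784149.1	Myotis brandtii	proline-rich receptor-like protein kinase PERK9	80.26	3.66e-152
XP_053785850.1	Miniopterus natalensis	endogenous retrovirus group K (ERVK) member 25	58.58	2.39e-142
XP_045047497.1	Eptesicus fuscus	toll-like receptor 4	88.57	4.03e-134
XP_071076901.1	Myotis lucifugus	kelch domain-containing protein 7B	75.07	7.86e-132
XP_053786695.1	Pteropus alecto	EF-hand calcium-binding domain-containing protein 3	53.98	9.15e-132
XP_024430562.2	Myotis davidii	vesicle-associated membrane protein 7	90.34	1.05e-118
XP_024407409.2	Rousettus aegyptiacus	mitotic spindle assembly checkpoint protein MAD2A	90.45	2.24e-116
XP_024414427.2	mouse	thioesterase superfamily member 7	77.39	1.72e-113
XP_045052948.3	Hipposideros armiger	Polyadenylation specificity factor subunit 5	74.44	6.70e-110
XP_045051350.1	Myotis brandtii	keratin-associated protein 10	97.84	5.94e-93
XP_045058910.2	Hipposideros armiger	phospholipase A2 inhibitor	69.49	9.20e-82
XP_053771141.1	Myotis davidii	protein NYNRIN-like	54.65	2.65e-76
XP_053779447.1	Miniopterus natalensis	cyclic nucleotide-binding domain-containing protein 2	76.39	7.15e-69
XP_053773395.1	Rousettus aegyptiacus	doublesex- and mab-3-related transcription factor C2	52.11	4.26e-53
XP_045053117.2	Hipposideros armiger	sorbin and SH3 domain-containing protein 2	70.73	2.75e-44
XP_053766423.1	Eptesicus fuscus	ribosomal protein L18	86.42	3.66e-41
XP_053779458.1	Phyllostomus discolor	translation initiation factor IF-2	62.90	1.94e-34
XP_071075791.1	Myotis brandtii	sperm acrosome membrane-associated protein 4	77.33	2.14e-33
XP_045044110.2	Eptesicus fuscus	spermatid nuclear transition protein 3	74.19	7.99e-29
XP_071076697.1	Pteropus vampyrus	vegetative cell wall protein gp1	82.55	1.90e-22
XP_053772343.1	Hipposideros armiger	LIM domain only protein	92.86	3.28e-17
XP_053769798.1	Phyllostomus discolor	collagen alpha-1(I) chain-like	85.00	3.23e-15
XP_045047205.2	human	DMRT like family C1	68.18	9.33e-9
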