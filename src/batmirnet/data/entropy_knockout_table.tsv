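node	degree	degree_probability	original_entropy	new_entropy	entropy_change
MYC	11	0.0104	1.2716	1.2154	-0.0562
BCL2	11	0.0104	1.2716	1.2311	-0.0405
UBA52	7	0.0208	1.2716	1.2471	-0.0245
KIF1B	3	0.0885	1.2716	1.2486	-0.0230
THBS1	4	0.0573	1.2716	1.2496	-0.0220
STX16	4	0.0573	1.2716	1.2496	-0.0220
VAMP1	4	0.0573	1.2716	1.2496	-0.0220
RAD54L2	3	0.0885	1.2716	1.2506	-0.0210
DEK	3	0.0885	1.2716	1.2514	-0.0202
CDC6	4	0.0573	1.2716	1.2518	-0.0199
FGFR1	3	0.0885	1.2716	1.2528	-0.0188
TRA2B	4	0.0573	1.2716	1.2541	-0.0176
CDKN1B	7	0.0208	1.2716	1.2544	-0.0173
GNL3L	3	0.0885	1.2716	1.2546	-0.0171
CCNF	2	0.1354	1.2716	1.2551	-0.0166
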