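species	IRF1	IRF2	IRF3	IRF4	IRF5	IRF7	IRF8	IRF9
Eptesicus fuscus	93.9	95.1	83.1	97.3	93.7	73.7	92.5	87.5
Hipposideros armiger	95.4	97.5	82.4	96.3	93.4	72.5	93.9	80.9
Miniopterus natalensis	96.9	96.0	81.5	81.5	94.6	75.2	96.0	86.2
Myotis brandtii	94.8	98.7	81.5	97.8	91.9	28.8	95.1	83.8
Myotis davidii	93.9	45.3	79.8	97.8	91.5	28.6	95.3	83.8
Myotis lucifugus	94.8	49.5	81.0	37.7	92.3	26.4	95.1	83.0
Phyllostomus discolor	99.4	96.3	89.7	89.8	95.2	82.0	96.7	94.9
Pteropus alecto	96.7	97.8	82.4	96.9	92.8	70.1	95.1	86.6
Pteropus vampyrus	96.7	49.8	82.2	78.1	93.0	69.8	94.6	86.6
Rousettus aegyptiacus	44.6	96.4	78.6	97.1	92.2	70.1	95.1	85.9
human	94.8	96.4	79.5	42.9	87.1	64.3	91.3	78.9
mouse	83.7	91.7	68.6	39.5	86.9	58.2	89.7	64.1
rat	84.6	86.1	71.1	39.9	87.5	58.6	87.1	63.9
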