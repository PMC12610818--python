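# batmirnet

Regulatory-genomics toolkit for studying antiviral adaptation in the common
vampire bat (*Desmodus rotundus*) — a species that tolerates a heavy viral
load without disease. The package implements the full analysis chain as a
tested, reusable library:

* **Homology & annotation** — Needleman–Wunsch / Smith–Waterman protein
  alignment (BLOSUM62, affine gaps), Karlin–Altschul E-values
  (`E = K·m·n·e^(−λS)`), homolog filtering at E ≤ 1e−5 and identity ≥ 50%,
  best-hit annotation transfer for uncharacterized proteins, and
  species × family identity matrices with an "all species average" row.
* **miRNA discovery** — an ungapped mismatch-bounded scan of ncRNAs against
  a mature-miRNA reference (length ≥ 18 nt, ≤ 2 mismatches, no gaps),
  ±50 nt precursor windows, minimum-free-energy folding and McCaskill-style
  base-pair probabilities under a simplified nearest-neighbour model, and
  thermodynamic filtering (MFE ≤ −20 kcal/mol plus an ensemble-diversity
  cut): `ED = 2·Σ_{i<j} p_ij(1 − p_ij)`.
* **Target networks** — high-confidence interaction filtering (binding
  score = 1, 3′-UTR site, validated accession) and assembly of a mixed
  miRNA–gene / gene–gene simple network with round-trip TSV/GraphML export.
* **Enrichment & features** — EASE-style modified Fisher enrichment
  (overlap decremented by one; conservative by construction), BH
  adjustment, Welch t and background-decile chi-square feature comparisons.
* **Network entropy** — degree-distribution Shannon entropy
  `H = −Σ_k p_k log p_k`, `p_k = n_k/N`, and single-node knockout ranking
  by the entropy change ΔH = H_new − H_original.
* **Synthetic data** — seeded generators with ground truth for every input
  (planted hairpin corpora with dinucleotide-shuffled decoys, interaction
  tables with controlled pass fractions, configuration-model networks,
  shifted feature tables, fixed-identity protein pairs), so the whole
  pipeline is verifiable end to end.

See `docs/methods.md` for the models, assumptions and design choices.

## Worked example

```python
from batmirnet import syndata, mirna, netent, targets_net, datasets

# a synthetic corpus with 6 planted hairpin precursors among 20 decoys
cfg = syndata.GeneratorConfig(seed=5, n_planted=6, n_decoys=20)
refs, hosts, truth = syndata.gen_mirna_corpus(cfg)

result = mirna.discover(hosts, refs)        # scan -> fold -> filter
print(len(result.hits), len(result.structural))
# 6 6        <- every planted hairpin found, all pass the MFE filter

c = result.structural[0]
print(f"{c.hit.mature_id} mfe={c.mfe:.1f} ed={c.ensemble_diversity:.1f}")
# mat-020 mfe=-55.3 ed=23.4

# the bundled high-confidence interaction set -> network -> knockout ranking
recs = targets_net.frame_to_records(datasets.mirna_target_interactions())
net = targets_net.build_network(targets_net.filter_interactions(recs))
top = netent.rank_by_entropy_change(net.graph)[0]
print(top.node_id, top.degree, round(top.entropy_change, 4))
# ABT1 1 -0.0437
```

The discovery numbers say all six planted precursors were recovered by the
scan and passed the stability filter (strongly negative MFE, here −55.3
kcal/mol for a clean ~20-bp stem). The knockout line identifies the node
whose removal shifts the degree-distribution entropy of the bundled
20-interaction network the most: in this small bipartite layer the
degree-1 gene class dominates the distribution, so removing one of those
genes (ties broken lexicographically) sharpens the distribution the most
and gives the most negative ΔH.

An end-to-end synthetic run, with artifacts and a summary JSON written to a
directory:

```bash
batmirnet -v run-all --seed 11 --outdir runs/demo
```

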