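# Methods

`batmirnet` re-implements, as a tested library, a genome-scale regulatory
analysis for the common vampire bat (*Desmodus rotundus*): homology-based
annotation transfer and family identity matrices, structure-based discovery
of novel miRNA precursors with thermodynamic filters, assembly of a
high-confidence miRNA–target network augmented with gene–gene association
edges, gene-set enrichment and genomic-feature statistics for the target
set, and a degree-distribution network-entropy knockout ranking of network
nodes. Because the original raw inputs (proteomes, a miRBase-style mature
set, target-prediction and association databases) are external services and
downloads, the package ships a synthetic-data module that generates every
input with known ground truth, so each stage can be verified end to end.

## Pairwise alignment and homology transfer

Alignments use Needleman–Wunsch (global) and Smith–Waterman (local) with
BLOSUM62 and affine gaps (a gap of length L costs `open + (L−1)·extend`,
default −11/−1); the ambiguity residue X scores 0 against everything. The
DP engine is Biopython's `PairwiseAligner`; the test suite pins local
scores to an exhaustive substring-pair search with an independent Gotoh
recursion.

Percent identity is `identities / alignment columns × 100` with gap columns
included in the denominator — the common tabular convention; reported
identities and column means are rounded half-up to one decimal. E-values
use the ungapped Karlin–Altschul closed form `E = K·m·n·e^(−λS)` with
BLOSUM62 defaults λ = 0.3176, K = 0.134 (config-exposed); heuristic seeded
search and gapped statistics are out of scope. Homologs are retained at
E ≤ 1e−5 and identity ≥ 50%. Annotation transfer takes one best hit per
uncharacterized protein with the deterministic tie-break (higher score,
lower E, higher identity, lexicographic subject id); proteins without a
passing hit are reported as "uncharacterized" rather than dropped.
Reciprocal-best-hit checking is deliberately not performed: the original
procedure was one-directional transfer plus manual curation, which a
deterministic tie-break replaces reproducibly. Identity matrices default to
global alignments (a local mode is available); species lacking a family
member leave a missing cell that is excluded from that column's mean.

## miRNA discovery

The scan slides every full-length mature miRNA along every ncRNA and keeps
ungapped windows with alignment length ≥ 18 nt and ≤ 2 Hamming mismatches
(T and U equivalent). Overlapping hits of the same (ncRNA, mature) pair
collapse to the lowest-mismatch, then leftmost window — a choice the
original procedure leaves open. Only the given orientation is scanned;
ncRNA records are treated as stranded transcripts. Each hit is extended by
50 nt on both sides (clamped at transcript ends; clamped windows are folded
rather than discarded) to form the precursor window.

### Energy model

Folding uses a deliberately simplified nearest-neighbour model: Watson–
Crick and GU pairs; stacking free energies (kcal/mol, Turner-like
magnitudes) for a pair directly enclosing another; a hairpin-loop closing
penalty by loop size (table for 3–9 nt, Jacobson–Stockmayer logarithmic
extrapolation beyond); minimum loop 3 nt; temperature 310.15 K. Pairs that
neither stack nor close a hairpin contribute zero — there are no multiloop,
internal-loop, bulge or dangle terms. MFE is computed by a Zuker-style DP
over nested structures (tables for "paired", "any structure", "at least one
pair"); the traceback reports a dot-bracket structure that achieves the
reported energy exactly.

Base-pair probabilities come from McCaskill-style inside/outside
recursions over the same ensemble, with Vienna-style per-nucleotide
rescaling of partition weights so that long stable windows do not overflow
double precision. Ensemble diversity is the expected base-pair distance
between two independent Boltzmann draws, `ED = 2·Σ_{i<j} p_ij(1 − p_ij)`.
Both MFE and the probability matrix are pinned to full structure
enumeration (tolerance 1e−9) for sequences up to 14 nt, and
`−RT·ln Z ≤ MFE` is asserted as an invariant.

### Filters and the ED direction

Candidates are retained when length ≥ 18, mismatches ≤ 2, MFE ≤ −20
kcal/mol and the ED criterion holds. The stated threshold "ED ≥ 15"
contradicts the accompanying candidate table, in which every retained
candidate has ED ≤ 14.7; the package therefore defaults to `ed_direction
= "le"` (consistent with the table evidence) and exposes `"ge"` as a flag,
asserting neither as the intended reading.

A limitation follows from the simplified energy model: with no penalty on
isolated pairs, the Boltzmann ensemble of a ~120 nt window is considerably
"floppier" than under a full thermodynamic parameter set, so window-level
ED values are larger than those a production folder reports and the ED cut
is not meaningful for synthetic corpora. Planted-recovery guarantees are
therefore stated at the scan + MFE level (where the planted stem controls
the outcome directly); the ED filter semantics are exercised on descriptor
tables, including the bundled 19-candidate reference set. Users wanting
production thermodynamics can plug any external folder into the engine
contract (an executable mapping FASTA to energy, dot-bracket and ED);
result tables record which engine produced them.

## Target filtering and network assembly

Candidate interactions are retained only if binding score = 1 (exact
equality on the stored decimal), binding region = 3′-UTR, and a validated
accession is present (optionally constrained to `MIRT\d+`). Binding
energies are carried into reports but never filtered on. The network is a
simple undirected graph — regulatory direction is kept only as an edge
attribute because the entropy formulas use undirected degree — with a
bipartite miRNA–gene layer plus a gene–gene association layer; duplicate
edges collapse, self-loops are dropped with a logged count, and an id used
as both miRNA and gene is rejected as ambiguous. Edge-list TSV and GraphML
exports round-trip exactly, node kinds included. Association edges are not
confidence-thresholded by default (an optional weight cut exists) since the
original integration step states none.

## Enrichment and feature statistics

Enrichment uses the EASE variant of the one-sided Fisher/hypergeometric
test: the overlap is decremented by one before the upper-tail sum, so
k ≤ 1 gives p = 1 and the statistic is uniformly conservative relative to
Fisher (property-tested). Terms need ≥ 2 list genes by default; the percent
column's denominator is the number of list genes with at least one
annotation in the category (logged), since the original table leaves the
denominator unstated. Benjamini–Hochberg adjustment is computed within each
annotation category and always emitted alongside the raw p-values; the
significance criterion itself is raw p < 0.05. Annotation systems are
user-supplied gene→term tables — the statistics, not any specific database,
are in scope.

Feature comparisons run a Welch two-sample t-test on raw values ("Student's
t" is implemented as Welch by default — safer for length distributions;
a pooled-variance mode exists) and a chi-square test of target counts over
background-decile bins against a uniform expectation. Decile binning is
rank-based, making the chi-square invariant under monotone transforms of
the feature (asserted as a test). Zero-variance features skip the t-test
with a logged reason but keep the chi-square.

## Network entropy and knockouts

Network entropy is the Shannon entropy of the degree-class distribution,
`H = −Σ_k p_k log p_k` with `p_k = n_k/N`, N the total node count
(including degree-0 nodes). Natural log is the default — the only base
that makes the reported entropy magnitudes plausible for a ~192-node
network with ≥ 6 degree classes — with bases 2 and 10 exposed. A
consistency computation justifies reading N as the total node count: the
five distinct reported degree probabilities (0.0104, 0.0208, 0.0573,
0.0885, 0.1354) are all within 0.01 of integer multiples of 1/192, and no
N ≤ 500 smaller than 192 achieves that; the test suite reproduces this
computation.

Knockouts default to full recomputation: the node and its incident edges
are removed, neighbour degrees decrement, and H is recomputed over the
remaining N−1 nodes, with survivors isolated by the removal kept as a
degree-0 class. Because the original procedure is not explicit, a
`class_only` mode (only the node leaves its own degree class) is also
provided; neither is asserted as "the" published semantics. Rankings sort
by ascending ΔH with ties broken by higher degree then lexicographic id;
tables round to 4 decimals while report objects keep full precision, and
`H_original + ΔH = H_new` holds to 1e−12 before rounding.

## Synthetic data

Generators are deterministic given the configuration (each draws from an
independent stream derived from the single seed): identical configs give
byte-identical outputs, and every emitted item appears exactly once in the
ground-truth table.

* **miRNA corpus** — each planted host carries random context of at least
  the flank length, a mature arm copied from a reference mature (mutated at
  ≤ 2 sites when a mutation rate is set), a 6–12 nt loop, and the reverse
  complement of the arm with bulge-free mismatches; the mature sits on the
  5′ arm by default (3′-arm planting is a flag). Decoys are
  Altschul–Erikson dinucleotide shuffles of planted-style sequences —
  composition preserved, stems destroyed. Defaults are 100 planted among
  900 decoys; the real scanned corpus size is unpublished, so these are
  explicit, configurable choices.
* **Interactions** — each row independently passes all three filters with
  probability `frac_pass`; failing rows violate a random non-empty subset
  of the criteria, recorded in the truth table.
* **Networks** — configuration-model graphs with rejection sampling
  (retry cap 1000) so the realisation is simple and matches the requested
  degree sequence exactly.
* **Features** — lengths are log-normal, GC is a clipped normal in (0,1),
  exon counts are shifted Poisson; target-group shifts are log-scale deltas
  for lengths and additive otherwise. Default shifts mirror the study's
  qualitative findings (longer transcripts and 3′-UTRs, modest GC and exon
  differences, no CDS-length effect).
* **Proteome pairs** — a random protein and a copy substituted at exactly
  `round((1 − t/100)·L)` positions for each requested identity t.

What the generators do **not** emulate: real genomic base composition and
repeat structure, codon constraints, homology between decoys and reference
matures, correlated features, or database-specific biases. Passing tests
therefore demonstrate algorithmic correctness under controlled conditions,
not performance on real genomes.

## Numerical choices and problem sizes

Tolerances: enumeration oracles 1e−9; entropy identities 1e−12; reported
tables one decimal (identities) or four decimals (entropies), half-up.
Reported reference tables round their three entropy columns independently,
so internal-consistency checks allow one unit in the fourth decimal. The
test suite sizes its simulations for quick turnaround (planted corpora of
tens of sequences; enumeration up to 14 nt; exhaustive alignment up to
~10 aa; 100 random graphs for knockout equivalence), and the acceptance
script runs the full default corpus (100 planted / 900 decoys). All
randomness in tests and scripts is seeded.
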