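"""Seeded synthetic-data generators for every input the pipeline consumes.

The study's external inputs (reference proteomes, a miRBase-like mature
miRNA set, target-prediction tables, protein-association networks, genomic
feature tables) are replaced here by generators with known ground truth:

* ncRNA corpora with planted hairpin precursors (mature arm + loop +
  reverse-complement arm) and dinucleotide-shuffled decoys;
* interaction tables with a controlled fraction passing the three
  high-confidence filters;
* configuration-model graphs realising a prescribed degree sequence;
* feature tables with specified location shifts between target genes and
  the genomic background;
* protein pairs mutated to a requested percent identity.

All generators are deterministic given the same :class:`GeneratorConfig`
(including its seed): identical configs give byte-identical outputs.
Coordinates are 0-based half-open; FASTA is written wrapped at 80 columns
with truth parameters as key=value pairs in the description.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DNA = "ACGT"
AMINO = "ACDEFGHIKLMNPQRSTVWY"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# stream tags so each generator draws from an independent, seed-derived stream
_STREAMS = {"mirna": 1, "interaction": 2, "network": 3, "feature": 4,
            "proteome": 5, "annotation": 6}


@dataclass(frozen=True)
class TruthRecord:
    item_id: str
    kind: str
    payload: dict


@dataclass
class TruthTable:
    """Ground truth for generated items; every item id appears exactly once."""

    records: list = field(default_factory=list)

    def __post_init__(self):
        ids = [r.item_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate item ids in truth table")

    def add(self, item_id: str, kind: str, **payload):
        if any(r.item_id == item_id for r in self.records):
            raise ValueError(f"duplicate truth id {item_id!r}")
        self.records.append(TruthRecord(item_id, kind, payload))

    def of_kind(self, kind: str) -> list:
        return [r for r in self.records if r.kind == kind]

    def __getitem__(self, item_id: str) -> TruthRecord:
        for r in self.records:
            if r.item_id == item_id:
                return r
        raise KeyError(item_id)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"item_id": r.item_id, "kind": r.kind, **r.payload}
                for r in self.records]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs for the synthetic study system.

    Defaults encode the conditions the pipeline is exercised under: 100
    planted precursors among 900 decoys (the real scan size is unpublished),
    50 nt flanks, a clean (mutation-free) mature arm, and a 50% pass
    fraction for interaction tables.
    """

    seed: int = 0
    # miRNA corpus
    n_reference: int = 30
    n_planted: int = 100
    n_decoys: int = 900
    flank_length: int = 50
    mutation_rate: float = 0.0
    plant_3prime_arm: bool = False
    # interactions
    n_interactions: int = 400
    frac_pass: float = 0.5
    # network
    degree_sequence: tuple = ()
    config_model_retries: int = 1000
    # features
    n_target: int = 200
    n_background: int = 2000
    feature_shifts: dict = field(default_factory=lambda: {
        "cds_length": 0.0, "transcript_length": 0.4, "genome_span": 0.3,
        "utr3_length": 0.5, "gc_content": 0.02, "exon_count": 2.0})
    # proteome pairs
    identity_targets: tuple = (100.0, 80.0, 40.0)
    protein_length: int = 300

    def __post_init__(self):
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must lie in [0, 1]")
        if not 0.0 <= self.frac_pass <= 1.0:
            raise ValueError("frac_pass must lie in [0, 1]")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[stream]])


# ---------------------------------------------------------------------------
# FASTA helpers
# ---------------------------------------------------------------------------

def write_fasta(seqs: dict, handle_or_path, descriptions: dict | None = None,
                width: int = 80) -> None:
    """Write sequences wrapped at 80 columns; descriptions (key=value text)
    go on the header line after the id."""
    descriptions = descriptions or {}

    def _write(fh):
        for sid, seq in seqs.items():
            desc = descriptions.get(sid, "")
            fh.write(f">{sid} {desc}".rstrip() + "\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")

    if hasattr(handle_or_path, "write"):
        _write(handle_or_path)
    else:
        with open(handle_or_path, "w") as fh:
            _write(fh)


def fasta_text(seqs: dict, descriptions: dict | None = None) -> str:
    buf = io.StringIO()
    write_fasta(seqs, buf, descriptions)
    return buf.getvalue()


def read_fasta(path) -> dict:
    seqs: dict[str, list] = {}
    order = []
    with open(path) as fh:
        cur = None
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                cur = line[1:].split()[0]
                seqs[cur] = []
                order.append(cur)
            elif cur is not None:
                seqs[cur].append(line)
    return {k: "".join(seqs[k]) for k in order}


# ---------------------------------------------------------------------------
# sequence utilities
# ---------------------------------------------------------------------------

def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(DNA), size=length))


def _mutate(rng: np.random.Generator, seq: str, n_sites: int) -> str:
    """Substitute n_sites distinct positions with a different base."""
    if n_sites == 0:
        return seq
    chars = list(seq)
    for pos in rng.choice(len(chars), size=n_sites, replace=False):
        alternatives = [b for b in DNA if b != chars[pos]]
        chars[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(chars)


def dinucleotide_shuffle(rng: np.random.Generator, seq: str) -> str:
    """Altschul-Erikson shuffle: permute the sequence while preserving its
    exact dinucleotide composition (random Eulerian walk over the
    letter-transition multigraph)."""
    if len(seq) < 3:
        return seq
    edges: dict[str, list] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    final = seq[-1]
    # choose a random last-exit edge per vertex such that following the last
    # edges from any vertex reaches the final letter (spanning condition of
    # the Eulerian-walk construction); the letter graph has <= 4 vertices so
    # rejection is cheap
    verts = [v for v in edges if v != final]
    for _ in range(10000):
        last = {v: edges[v][int(rng.integers(len(edges[v])))] for v in verts}
        ok = True
        for v in verts:
            cur, hops = v, 0
            while cur != final and cur in last and hops <= len(verts):
                cur = last[cur]
                hops += 1
            if cur != final:
                ok = False
                break
        if ok:
            break
    else:
        raise RuntimeError("dinucleotide shuffle: no valid last-edge set found")
    walk_edges: dict[str, list] = {}
    for v, lst in edges.items():
        rest = list(lst)
        if v in last:
            rest.remove(last[v])
        rng.shuffle(rest)
        if v in last:
            rest.append(last[v])
        walk_edges[v] = rest[::-1]  # pop() takes from the front order
    out = [seq[0]]
    cur = seq[0]
    for _ in range(len(seq) - 1):
        cur = walk_edges[cur].pop()
        out.append(cur)
    return "".join(out)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def gen_mirna_corpus(cfg: GeneratorConfig):
    """Reference mature set, host ncRNAs with planted hairpins, and decoys.

    Each planted host contains: random 5' context of at least flank_length
    nt, the mature arm (a reference mature mutated at <= 2 sites), a 6-12 nt
    loop, the reverse complement of the arm with bulge-free mismatches at
    ``mutation_rate``, and random 3' context.  Decoys are dinucleotide
    shuffles of planted-style sequences, destroying any stable stem.
    """
    rng = cfg.rng("mirna")
    truth = TruthTable()
    refs = {f"mat-{i:03d}": random_dna(rng, int(rng.integers(18, 26)))
            for i in range(cfg.n_reference)}
    hosts: dict[str, str] = {}
    ref_ids = list(refs)
    for i in range(cfg.n_planted):
        hid = f"planted_{i:04d}"
        mid = ref_ids[int(rng.integers(len(ref_ids)))] if ref_ids else None
        if mid is None:
            raise ValueError("cannot plant hairpins without reference matures")
        mature = refs[mid]
        arm_mut = min(int(rng.binomial(len(mature), cfg.mutation_rate)), 2)
        arm = _mutate(rng, mature, arm_mut)
        loop = random_dna(rng, int(rng.integers(6, 13)))
        star = reverse_complement(arm)
        star_mut = int(rng.binomial(len(star), cfg.mutation_rate))
        star = _mutate(rng, star, star_mut)
        left = random_dna(rng, cfg.flank_length + int(rng.integers(0, 31)))
        right = random_dna(rng, cfg.flank_length + int(rng.integers(0, 31)))
        if cfg.plant_3prime_arm:
            seq = left + star + loop + arm + right
            start = len(left) + len(star) + len(loop)
        else:
            seq = left + arm + loop + star + right
            start = len(left)
        hosts[hid] = seq
        truth.add(hid, "planted_mirna", mature_id=mid, start=start,
                  end=start + len(arm), arm_mismatches=arm_mut,
                  star_mismatches=star_mut, loop_length=len(loop))
    for i in range(cfg.n_decoys):
        did = f"decoy_{i:04d}"
        mid = ref_ids[int(rng.integers(len(ref_ids)))] if ref_ids else None
        if mid is None:
            template = random_dna(rng, 2 * cfg.flank_length + 60)
        else:
            mature = refs[mid]
            loop = random_dna(rng, int(rng.integers(6, 13)))
            template = (random_dna(rng, cfg.flank_length) + mature + loop
                        + reverse_complement(mature)
                        + random_dna(rng, cfg.flank_length))
        hosts[did] = dinucleotide_shuffle(rng, template)
        truth.add(did, "decoy", length=len(hosts[did]))
    return refs, hosts, truth


def gen_interaction_table(cfg: GeneratorConfig, mirna_ids: list[str],
                          gene_ids: list[str]):
    """Interaction rows of which a Bernoulli(frac_pass) fraction satisfies
    all three high-confidence criteria (score = 1, 3UTR, validated id);
    every other row violates at least one, with the violations recorded."""
    rng = cfg.rng("interaction")
    n = cfg.n_interactions
    if n > 0 and (not mirna_ids or not gene_ids):
        raise ValueError("id lists must be non-empty when interactions are requested")
    truth = TruthTable()
    rows = []
    for i in range(n):
        rid = f"int_{i:05d}"
        mirna = mirna_ids[int(rng.integers(len(mirna_ids)))]
        gene = gene_ids[int(rng.integers(len(gene_ids)))]
        energy = round(float(rng.uniform(-40.0, -15.0)), 1)
        passing = bool(rng.random() < cfg.frac_pass)
        if passing:
            score, region, validated = 1.0, "3UTR", f"MIRT{rng.integers(100000, 999999)}"
            violations = []
        else:
            choices = ["score", "region", "validated"]
            k = int(rng.integers(1, 4))
            violations = sorted(rng.choice(choices, size=k, replace=False).tolist())
            score = round(float(rng.uniform(0.5, 0.99)), 2) if "score" in violations else 1.0
            region = ("5UTR", "CDS")[int(rng.integers(2))] if "region" in violations else "3UTR"
            validated = "" if "validated" in violations else f"MIRT{rng.integers(100000, 999999)}"
        rows.append((mirna, gene, f"NM_{rng.integers(100000, 999999)}",
                     score, region, energy, validated))
        truth.add(rid, "passing_interaction" if passing else "failing_interaction",
                  row=i, violations=violations)
    table = pd.DataFrame(rows, columns=["mirna", "gene", "coding_protein",
                                        "binding_score", "region",
                                        "binding_energy", "validated_id"])
    return table, truth


def gen_network(cfg: GeneratorConfig, degree_sequence=None):
    """Configuration-model simple graph with exactly the requested degree
    sequence (self-loops / multi-edges rejected and resampled)."""
    import networkx as nx

    seq = list(degree_sequence if degree_sequence is not None else cfg.degree_sequence)
    total = sum(seq)
    if total % 2 != 0:
        raise ValueError(f"degree sequence sums to {total}, which is odd")
    rng = cfg.rng("network")
    for _ in range(cfg.config_model_retries):
        g = nx.configuration_model(seq, seed=int(rng.integers(2 ** 31)))
        if nx.number_of_selfloops(g) == 0 and max(
                (len(g[u][v]) for u, v in g.edges()), default=1) == 1:
            simple = nx.Graph(g)
            assert sorted(d for _, d in simple.degree()) == sorted(seq)
            return simple
    raise RuntimeError(
        f"no simple realisation found in {cfg.config_model_retries} attempts")


# baseline feature distributions for the genomic background: lengths are
# log-normal, GC bounded in (0,1), exon counts positive integers
_FEATURE_BASELINES = {
    "cds_length": ("lognormal", 7.2, 0.6),
    "transcript_length": ("lognormal", 8.0, 0.7),
    "genome_span": ("lognormal", 9.5, 1.0),
    "utr3_length": ("lognormal", 6.2, 0.8),
    "gc_content": ("gc", 0.45, 0.06),
    "exon_count": ("exon", 7.0, None),
}


def gen_feature_table(cfg: GeneratorConfig) -> pd.DataFrame:
    """Gene-feature table with a ``group`` column; target-group features are
    shifted by ``feature_shifts`` (log-scale deltas for lengths, additive
    for GC and exon count)."""
    if cfg.n_target < 2 or cfg.n_background < 2:
        raise ValueError("need at least 2 genes per group")
    rng = cfg.rng("feature")
    rows = {}
    groups = (["target"] * cfg.n_target) + (["background"] * cfg.n_background)
    n = len(groups)
    shifts = dict(cfg.feature_shifts)
    rows["gene"] = [f"g{i:05d}" for i in range(n)]
    rows["group"] = groups
    is_target = np.array([g == "target" for g in groups])
    for feat, (kind, a, b) in _FEATURE_BASELINES.items():
        delta = shifts.get(feat, 0.0)
        if kind == "lognormal":
            mu = np.where(is_target, a + delta, a)
            rows[feat] = np.round(rng.lognormal(mu, b), 1)
        elif kind == "gc":
            mean = np.where(is_target, a + delta, a)
            rows[feat] = np.clip(rng.normal(mean, b), 0.01, 0.99).round(4)
        else:  # exon count
            lam = np.where(is_target, a + delta, a)
            rows[feat] = 1 + rng.poisson(np.maximum(lam, 0.0))
    return pd.DataFrame(rows)


def gen_proteome_pair(cfg: GeneratorConfig):
    """For each requested identity t, a random protein and a copy mutated at
    round((1 - t/100) * L) positions; truth records the pair and t."""
    rng = cfg.rng("proteome")
    truth = TruthTable()
    queries: dict[str, str] = {}
    references: dict[str, str] = {}
    for t in cfg.identity_targets:
        if not 0.0 < t <= 100.0:
            raise ValueError("identity targets must lie in (0, 100]")
        L = cfg.protein_length
        base = "".join(rng.choice(list(AMINO), size=L))
        n_mut = int(round((1.0 - t / 100.0) * L))
        chars = list(base)
        for pos in rng.choice(L, size=n_mut, replace=False):
            alternatives = [a for a in AMINO if a != chars[pos]]
            chars[pos] = alternatives[int(rng.integers(len(alternatives)))]
        qid, rid = f"q_t{t:g}", f"r_t{t:g}"
        references[rid] = base
        queries[qid] = "".join(chars)
        truth.add(qid, "homolog_pair", partner=rid, target_identity=t,
                  mutated_sites=n_mut)
    return queries, references, truth


def gen_annotation_table(cfg: GeneratorConfig, universe: list[str],
                         n_terms: int = 20, categories=("GO_BP", "KEGG")) -> pd.DataFrame:
    """Random gene -> term annotation table over the universe (pipeline
    convenience; enrichment statistics are exercised against it)."""
    rng = cfg.rng("annotation")
    rows = []
    for cat in categories:
        for t in range(n_terms):
            size = int(rng.integers(3, max(4, len(universe) // 4)))
            for g in rng.choice(universe, size=min(size, len(universe)), replace=False):
                rows.append((g, cat, f"{cat}:term{t:03d}"))
    return pd.DataFrame(rows, columns=["gene", "category", "term"])
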