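"""Pairwise protein alignment, homolog filtering and annotation transfer.

Implements the comparative-proteomics layer of the vampire-bat analysis:
Needleman-Wunsch / Smith-Waterman alignment with affine gap penalties,
Karlin-Altschul E-values, homolog detection at identity/E-value thresholds,
best-hit functional annotation transfer for uncharacterized proteins (UCPs),
and per-family identity matrices with an "all species average" row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

# BLAST-style ungapped BLOSUM62 statistics; exposed so callers can substitute
# engine-specific gapped values.
DEFAULT_LAMBDA = 0.3176
DEFAULT_K = 0.134
DEFAULT_EVALUE_MAX = 1e-5
DEFAULT_IDENTITY_MIN = 50.0

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (table formatting convention)."""
    factor = 10.0 ** ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def _blosum62_x_neutral() -> substitution_matrices.Array:
    """BLOSUM62 with the ambiguity residue X scored 0 against everything."""
    m = substitution_matrices.load("BLOSUM62").copy()
    alphabet = m.alphabet
    if "X" in alphabet:
        for a in alphabet:
            m["X", a] = 0.0
            m[a, "X"] = 0.0
    return m


@dataclass(frozen=True)
class AlignmentResult:
    """One optimal pairwise alignment and its summary statistics.

    ``percent_identity`` uses the total number of alignment columns
    (gap columns included) as denominator, the usual tabular convention.
    """

    query_id: str
    subject_id: str
    mode: str
    raw_score: int
    aligned_columns: int
    identities: int
    gap_columns: int
    percent_identity: float
    evalue: float = float("nan")

    def __post_init__(self):
        if not 0 <= self.identities <= max(self.aligned_columns, 0):
            raise ValueError("identities must lie in [0, aligned_columns]")


@dataclass(frozen=True)
class AnnotationTransfer:
    ucp_id: str
    homolog_species: str
    transferred_annotation: str
    percent_identity: float
    evalue: float


@dataclass
class IdentityMatrix:
    """Species x family-member percent-identity table plus column means."""

    values: pd.DataFrame
    column_means: pd.Series = field(init=False)

    def __post_init__(self):
        self.column_means = column_means(self.values)

    def to_frame(self, mean_label: str = "All species average") -> pd.DataFrame:
        out = self.values.copy()
        out.loc[mean_label] = [round_half_up(v, 1) if np.isfinite(v) else np.nan
                               for v in self.column_means]
        return out


def column_means(values: pd.DataFrame) -> pd.Series:
    """Per-column mean over non-missing cells, rounded to one decimal
    (half-up), matching the reporting precision of identity tables."""
    means = values.mean(axis=0, skipna=True)
    return means.map(lambda v: round_half_up(v, 1) if np.isfinite(v) else np.nan)


def _check_protein(seq: str, name: str) -> str:
    if not seq:
        raise ValueError(f"empty sequence for argument {name!r}")
    s = seq.upper()
    bad = set(s) - PROTEIN_ALPHABET
    if bad:
        raise ValueError(f"argument {name!r} contains non-protein letters {sorted(bad)}")
    return s


def _make_aligner(mode: str, matrix_name: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    if matrix_name.upper() == "BLOSUM62":
        aligner.substitution_matrix = _blosum62_x_neutral()
    else:
        aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    # first gapped column costs gap_open, each further column gap_extend
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def pairwise_align(
    a: str,
    b: str,
    mode: str = "global",
    matrix: str = "BLOSUM62",
    gap_open: float = -11.0,
    gap_extend: float = -1.0,
    query_id: str = "query",
    subject_id: str = "subject",
) -> AlignmentResult:
    """Optimal global (Needleman-Wunsch) or local (Smith-Waterman) alignment.

    Affine gap model: a gap of length L costs ``gap_open + (L-1)*gap_extend``.
    A local alignment whose best score is not positive is reported as the
    empty alignment with raw_score 0.
    """
    if mode not in ("global", "local"):
        raise ValueError(f"unknown mode {mode!r}")
    sa = _check_protein(a, "a")
    sb = _check_protein(b, "b")
    aligner = _make_aligner(mode, matrix, gap_open, gap_extend)
    alignments = aligner.align(sa, sb)
    score = alignments.score
    if mode == "local" and score <= 0:
        return AlignmentResult(query_id, subject_id, mode, 0, 0, 0, 0, 0.0)
    aln = alignments[0]
    counts = aln.counts()
    aligned_columns = counts.identities + counts.mismatches + counts.gaps
    pid = 100.0 * counts.identities / aligned_columns if aligned_columns else 0.0
    return AlignmentResult(
        query_id=query_id,
        subject_id=subject_id,
        mode=mode,
        raw_score=int(round(score)),
        aligned_columns=int(aligned_columns),
        identities=int(counts.identities),
        gap_columns=int(counts.gaps),
        percent_identity=pid,
    )


def karlin_altschul_evalue(raw_score: float, m: int, n: int,
                           lambda_: float = DEFAULT_LAMBDA,
                           K: float = DEFAULT_K) -> float:
    """Expected number of chance local alignments scoring >= raw_score:
    E = K * m * n * exp(-lambda * S)."""
    if lambda_ <= 0 or K <= 0:
        raise ValueError("lambda_ and K must be positive")
    if m < 1 or n < 1:
        raise ValueError("sequence lengths must be >= 1")
    return K * m * n * math.exp(-lambda_ * raw_score)


HIT_COLUMNS = ["query_id", "subject_id", "raw_score", "aligned_columns",
               "identities", "percent_identity", "evalue"]


def find_homologs(
    queries: dict[str, str],
    references: dict[str, str],
    e_max: float = DEFAULT_EVALUE_MAX,
    id_min: float = DEFAULT_IDENTITY_MIN,
    lambda_: float = DEFAULT_LAMBDA,
    K: float = DEFAULT_K,
    **align_kwargs,
) -> pd.DataFrame:
    """All-vs-all local alignment followed by the study's homolog filter:
    E-value <= e_max AND percent identity >= id_min.

    Returns hit rows sorted by (query_id, ascending evalue).
    """
    if not queries or not references:
        raise ValueError("queries and references must be non-empty")
    rows = []
    for qid, qseq in queries.items():
        for sid, sseq in references.items():
            res = pairwise_align(qseq, sseq, mode="local",
                                 query_id=qid, subject_id=sid, **align_kwargs)
            ev = karlin_altschul_evalue(res.raw_score, len(qseq), len(sseq),
                                        lambda_=lambda_, K=K)
            rows.append((qid, sid, res.raw_score, res.aligned_columns,
                         res.identities, res.percent_identity, ev))
    hits = pd.DataFrame(rows, columns=HIT_COLUMNS)
    return filter_hits(hits, e_max=e_max, id_min=id_min)


def filter_hits(hits: pd.DataFrame, e_max: float = DEFAULT_EVALUE_MAX,
                id_min: float = DEFAULT_IDENTITY_MIN) -> pd.DataFrame:
    """Apply the E-value/identity retention criteria to a precomputed hit
    table and sort by (query, ascending evalue)."""
    keep = (hits["evalue"] <= e_max) & (hits["percent_identity"] >= id_min)
    out = hits.loc[keep].sort_values(["query_id", "evalue"], kind="mergesort")
    return out.reset_index(drop=True)


def transfer_annotations(
    ucp_hits: pd.DataFrame,
    reference_annotations: dict[str, str],
    ucp_ids: list[str] | None = None,
    subject_species: dict[str, str] | None = None,
) -> list[AnnotationTransfer]:
    """Best-hit annotation transfer for uncharacterized proteins.

    One transfer per UCP; the winning hit is chosen by (higher raw_score,
    lower evalue, higher identity, lexicographically smaller subject_id).
    UCPs with no passing hit are reported as "uncharacterized".
    """
    subject_species = subject_species or {}
    if ucp_ids is None:
        ucp_ids = list(dict.fromkeys(ucp_hits["query_id"]))
    out = []
    for ucp in ucp_ids:
        sub = ucp_hits[ucp_hits["query_id"] == ucp]
        if sub.empty:
            out.append(AnnotationTransfer(ucp, "", "uncharacterized",
                                          float("nan"), float("nan")))
            continue
        best = min(
            sub.itertuples(index=False),
            key=lambda r: (-r.raw_score, r.evalue, -r.percent_identity, r.subject_id),
        )
        out.append(AnnotationTransfer(
            ucp_id=ucp,
            homolog_species=subject_species.get(best.subject_id, best.subject_id),
            transferred_annotation=reference_annotations.get(
                best.subject_id, "uncharacterized"),
            percent_identity=best.percent_identity,
            evalue=best.evalue,
        ))
    return out


def identity_matrix(
    family_sets: dict[str, dict[str, str]],
    reference_species: str,
    mode: str = "global",
    **align_kwargs,
) -> IdentityMatrix:
    """Per-family conservation matrix against one reference species.

    Cell (species s, member f) is the percent identity of the pairwise
    alignment between the reference species' member f and species s member f;
    species lacking a member leave the cell missing and are excluded from
    that column's mean.
    """
    if reference_species not in family_sets:
        raise ValueError(f"reference species {reference_species!r} absent")
    ref = family_sets[reference_species]
    if not ref:
        raise ValueError("reference species has no family members")
    members = list(ref)
    others = [s for s in family_sets if s != reference_species]
    values = pd.DataFrame(index=others, columns=members, dtype=float)
    for sp in others:
        for f in members:
            seq = family_sets[sp].get(f)
            if seq is None:
                continue
            res = pairwise_align(ref[f], seq, mode=mode, **align_kwargs)
            values.loc[sp, f] = res.percent_identity
    return IdentityMatrix(values)
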