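"""Structure-based novel-miRNA discovery.

The pipeline stages, in the order they run:

1. ``scan_matches`` — ungapped, mismatch-bounded scan of host ncRNAs against
   a reference set of mature miRNAs (alignment length >= 18 nt, <= 2
   mismatches, no gaps).
2. ``extract_precursor`` — the matched region plus 50 nt of flanking sequence
   on each side, clamped at the transcript ends, as the putative stem-loop
   precursor.
3. ``fold_mfe`` / ``partition_bp_probs`` / ``ensemble_diversity`` — minimum
   free energy, dot-bracket structure, base-pair probabilities and ensemble
   diversity (ED) under a simplified nearest-neighbour energy model
   (Watson-Crick + GU stacking terms and a hairpin-loop size penalty).
4. ``filter_candidates`` — thermodynamic filtering (MFE <= -20 kcal/mol and
   an ED cut, default ED <= 15) producing a report table with columns
   miRNA / sequence / length / mismatch / MFE / ED.

Energies are kcal/mol throughout; coordinates are 0-based half-open.
"""

from __future__ import annotations

import math
import shlex
import subprocess
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

GAS_CONSTANT = 0.0019872  # kcal / (mol K)
RNA_ALPHABET = "ACGU"
_BASE_INDEX = {b: i for i, b in enumerate(RNA_ALPHABET)}

# canonical pairs, index into the stack table
_PAIRS = ("AU", "CG", "GC", "UA", "GU", "UG")
_PAIR_INDEX = {p: i for i, p in enumerate(_PAIRS)}

# stack free energies (kcal/mol) for outer pair 5'i-j3' on inner pair
# (i+1, j-1); loosely Turner-like magnitudes, symmetrised, GU wobble allowed
_STACK = np.array([
    # inner: AU    CG    GC    UA    GU    UG      outer:
    [-0.9, -2.2, -2.1, -1.1, -0.6, -1.4],  # AU
    [-2.1, -3.3, -2.4, -2.1, -1.4, -2.1],  # CG
    [-2.4, -3.4, -3.3, -2.2, -1.5, -2.5],  # GC
    [-1.3, -2.4, -2.1, -0.9, -1.0, -1.3],  # UA
    [-1.3, -2.5, -2.1, -1.4, -0.5, +1.3],  # GU
    [-1.0, -1.5, -1.4, -0.6, +0.3, -0.5],  # UG
])

# hairpin-loop closing penalty by unpaired loop size (kcal/mol)
_HAIRPIN = {3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.4}


@dataclass(frozen=True)
class EnergyModel:
    """Simplified nearest-neighbour RNA energy model.

    Structures are scored additively: each base pair directly stacked on
    another contributes a (negative) stacking energy, each hairpin-closing
    pair pays a loop-size penalty, and all other pairs contribute zero.
    """

    stack: np.ndarray = field(default_factory=lambda: _STACK.copy())
    hairpin: dict = field(default_factory=lambda: dict(_HAIRPIN))
    min_loop: int = 3
    temperature: float = 310.15  # Kelvin

    def __post_init__(self):
        if self.min_loop < 3:
            raise ValueError("min_loop must be >= 3")

    def hairpin_penalty(self, loop_size: int) -> float:
        if loop_size in self.hairpin:
            return self.hairpin[loop_size]
        # Jacobson-Stockmayer logarithmic extrapolation beyond the table
        largest = max(self.hairpin)
        return self.hairpin[largest] + 1.75 * GAS_CONSTANT * 310.15 * math.log(
            loop_size / largest)

    def pair_index(self, a: str, b: str) -> int | None:
        return _PAIR_INDEX.get(a + b)

    def stack_energy(self, outer: int, inner: int) -> float:
        return float(self.stack[outer, inner])


DEFAULT_MODEL = EnergyModel()


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def _encode(seq: str, record: str = "sequence") -> np.ndarray:
    s = to_rna(seq)
    bad = set(s) - set(RNA_ALPHABET)
    if bad:
        raise ValueError(
            f"record {record!r} contains characters outside A/C/G/U/T: {sorted(bad)}")
    return np.fromiter((_BASE_INDEX[c] for c in s), dtype=np.int8, count=len(s))


# pairable lookup as 4x4 boolean / pair-type index matrix
_PAIR_TYPE = np.full((4, 4), -1, dtype=np.int8)
for _p, _i in _PAIR_INDEX.items():
    _PAIR_TYPE[_BASE_INDEX[_p[0]], _BASE_INDEX[_p[1]]] = _i


# ---------------------------------------------------------------------------
# stage 1: mature-miRNA scan
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MatureHit:
    """An ungapped full-length match of a mature miRNA inside an ncRNA."""

    ncrna_id: str
    mature_id: str
    start: int
    end: int
    length: int
    mismatches: int
    gapless: bool = True

    def __post_init__(self):
        if self.end - self.start != self.length:
            raise ValueError("end - start must equal length")


def scan_matches(
    ncrnas: dict[str, str],
    mature_reference: dict[str, str],
    min_len: int = 18,
    max_mismatch: int = 2,
) -> list[MatureHit]:
    """Slide every full-length mature sequence along every ncRNA and report
    ungapped windows with at most ``max_mismatch`` Hamming mismatches.

    Matures shorter than ``min_len`` cannot produce hits.  Overlapping hits
    of the same (ncRNA, mature) pair are collapsed to the lowest-mismatch
    (then leftmost) window.
    """
    matures = {}
    for mid, mseq in mature_reference.items():
        arr = _encode(mseq, mid)
        if len(arr) >= min_len:
            matures[mid] = arr
    hits: list[MatureHit] = []
    for nid, nseq in ncrnas.items():
        narr = _encode(nseq, nid)
        for mid, marr in matures.items():
            L = len(marr)
            if len(narr) < L:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(narr, L)
            mism = (windows != marr).sum(axis=1)
            starts = np.nonzero(mism <= max_mismatch)[0]
            if starts.size == 0:
                continue
            hits.extend(_collapse_overlaps(nid, mid, L, starts, mism[starts]))
    return hits


def _collapse_overlaps(nid: str, mid: str, length: int,
                       starts: np.ndarray, mismatches: np.ndarray) -> list[MatureHit]:
    """Merge clusters of mutually overlapping windows, keeping per cluster
    the hit with the fewest mismatches (ties: leftmost)."""
    out = []
    cluster: list[tuple[int, int]] = []
    cluster_end = -1
    for s, m in zip(starts.tolist(), mismatches.tolist()):
        if cluster and s >= cluster_end:
            out.append(_best_of(nid, mid, length, cluster))
            cluster = []
        cluster.append((s, m))
        cluster_end = s + length
    if cluster:
        out.append(_best_of(nid, mid, length, cluster))
    return out


def _best_of(nid, mid, length, cluster):
    m, s = min((m, s) for s, m in cluster)
    return MatureHit(nid, mid, s, s + length, length, m)


# ---------------------------------------------------------------------------
# stage 2: precursor window extraction
# ---------------------------------------------------------------------------

@dataclass
class PrecursorCandidate:
    """A mature hit together with its flanked precursor window and, once
    scored, its thermodynamic descriptors."""

    hit: MatureHit
    window_start: int
    window_end: int
    precursor_seq: str
    mfe: float | None = None
    structure: str | None = None
    ensemble_diversity: float | None = None
    pass_mfe: bool | None = None
    pass_ed: bool | None = None
    engine: str = ""


def extract_precursor(ncrna_seq: str, hit: MatureHit, flank: int = 50) -> PrecursorCandidate:
    """Flanked precursor window [max(0, start-flank), min(len, end+flank)),
    emitted as RNA (T -> U)."""
    n = len(ncrna_seq)
    if not (0 <= hit.start < hit.end <= n):
        raise ValueError(f"hit {hit} outside sequence of length {n}")
    ws = max(0, hit.start - flank)
    we = min(n, hit.end + flank)
    return PrecursorCandidate(hit, ws, we, to_rna(ncrna_seq[ws:we]))


# ---------------------------------------------------------------------------
# stage 3: thermodynamics
# ---------------------------------------------------------------------------

def structure_energy(seq: str, pairs: set[tuple[int, int]],
                     model: EnergyModel = DEFAULT_MODEL) -> float:
    """Additive energy of a nested structure under the model: stacking for
    directly nested pairs, a loop penalty for hairpin-closing pairs, zero
    otherwise."""
    arr = _encode(seq)
    energy = 0.0
    pairset = {(min(i, j), max(i, j)) for i, j in pairs}
    for i, j in pairset:
        pt = _PAIR_TYPE[arr[i], arr[j]]
        if pt < 0:
            raise ValueError(f"positions {i},{j} cannot pair")
        if j - i - 1 < model.min_loop:
            raise ValueError(f"loop of pair ({i},{j}) below min_loop")
        if (i + 1, j - 1) in pairset:
            inner = _PAIR_TYPE[arr[i + 1], arr[j - 1]]
            energy += model.stack_energy(pt, inner)
        elif not any(i < a < b < j for a, b in pairset):
            energy += model.hairpin_penalty(j - i - 1)
    return energy


def _dp_tables(arr: np.ndarray, model: EnergyModel):
    """Minimum-energy tables (inclusive [a, b] indexing, padded so that
    ``W[b+1, b]`` reads 0 for an empty region).

    V[i,j]  — best energy of [i,j] given (i,j) paired (inf if unpairable)
    W[a,b]  — best energy of [a,b], any structure (0 for the open chain)
    W1[a,b] — best energy of [a,b] over structures with at least one pair
    """
    n = len(arr)
    INF = np.inf
    V = np.full((n, n), INF)
    W = np.zeros((n + 2, n + 2))
    W1 = np.full((n + 2, n + 2), INF)
    pt = _PAIR_TYPE[arr[:, None], arr[None, :]]
    for span in range(0, n):
        for i in range(0, n - span):
            j = i + span
            p = pt[i, j] if span >= model.min_loop + 1 else -1
            if p >= 0:
                best = model.hairpin_penalty(j - i - 1)
                ip = pt[i + 1, j - 1]
                if ip >= 0 and (j - 1) - (i + 1) - 1 >= model.min_loop:
                    best = min(best, model.stack_energy(p, ip) + V[i + 1, j - 1])
                if W1[i + 1, j - 1] < INF:  # interior pair not (i+1, j-1)
                    best = min(best, W1[i + 1, j - 1])
                V[i, j] = best
            a, b = i, j
            w = W[a + 1, b] if b >= a + 1 else 0.0
            w1 = W1[a + 1, b] if b >= a + 1 else INF
            ks = np.arange(a + model.min_loop + 1, b + 1)
            if ks.size:
                vals = V[a, ks] + W[ks + 1, b]
                finite = vals[np.isfinite(vals)]
                if finite.size:
                    m = float(finite.min())
                    w = min(w, m)
                    w1 = min(w1, m)
            W[a, b] = min(w, 0.0)
            W1[a, b] = w1
    return V, W, W1


def _traceback(arr, model, V, W, W1, a, b, pairs, mode="W"):
    INF = np.inf
    eps = 1e-9
    if b < a:
        return
    if mode == "W":
        target = W[a, b]
        if abs((W[a + 1, b] if b >= a + 1 else 0.0) - target) < eps:
            _traceback(arr, model, V, W, W1, a + 1, b, pairs, "W")
            return
        for k in range(a + model.min_loop + 1, b + 1):
            rest = W[k + 1, b] if k + 1 <= b else 0.0
            if np.isfinite(V[a, k]) and abs(V[a, k] + rest - target) < eps:
                pairs.append((a, k))
                _traceback(arr, model, V, W, W1, a, k, pairs, "V")
                _traceback(arr, model, V, W, W1, k + 1, b, pairs, "W")
                return
        # empty chain (target 0)
        return
    if mode == "W1":
        target = W1[a, b]
        if b >= a + 1 and np.isfinite(W1[a + 1, b]) and abs(W1[a + 1, b] - target) < eps:
            _traceback(arr, model, V, W, W1, a + 1, b, pairs, "W1")
            return
        for k in range(a + model.min_loop + 1, b + 1):
            rest = W[k + 1, b] if k + 1 <= b else 0.0
            if np.isfinite(V[a, k]) and abs(V[a, k] + rest - target) < eps:
                pairs.append((a, k))
                _traceback(arr, model, V, W, W1, a, k, pairs, "V")
                _traceback(arr, model, V, W, W1, k + 1, b, pairs, "W")
                return
        raise AssertionError("W1 traceback failed")
    # mode == "V": (a, b) already recorded as a pair
    pt = _PAIR_TYPE[arr[a], arr[b]]
    target = V[a, b]
    if abs(model.hairpin_penalty(b - a - 1) - target) < eps:
        return
    ip = _PAIR_TYPE[arr[a + 1], arr[b - 1]]
    if ip >= 0 and (b - 1) - (a + 1) - 1 >= model.min_loop and \
            np.isfinite(V[a + 1, b - 1]) and \
            abs(model.stack_energy(pt, ip) + V[a + 1, b - 1] - target) < eps:
        pairs.append((a + 1, b - 1))
        _traceback(arr, model, V, W, W1, a + 1, b - 1, pairs, "V")
        return
    if np.isfinite(W1[a + 1, b - 1]) and abs(W1[a + 1, b - 1] - target) < eps:
        _traceback(arr, model, V, W, W1, a + 1, b - 1, pairs, "W1")
        return
    raise AssertionError("V traceback failed")


def fold_mfe(seq: str, model: EnergyModel = DEFAULT_MODEL) -> tuple[float, str]:
    """Minimum free energy and a dot-bracket structure achieving it.

    Dynamic-programming optimum over nested structures with hairpin loops of
    at least ``model.min_loop`` unpaired bases.  A sequence that cannot form
    any stabilising structure folds to the open chain (0.0, all dots).
    """
    arr = _encode(seq)
    n = len(arr)
    if n < 2 * 1 + model.min_loop + 1:
        return 0.0, "." * n
    V, W, W1 = _dp_tables(arr, model)
    mfe = float(W[0, n - 1])
    pairs: list[tuple[int, int]] = []
    _traceback(arr, model, V, W, W1, 0, n - 1, pairs)
    db = ["."] * n
    for i, j in pairs:
        db[i], db[j] = "(", ")"
    return mfe, "".join(db)


def partition_bp_probs(seq: str, model: EnergyModel = DEFAULT_MODEL) -> np.ndarray:
    """Base-pair probability matrix from inside/outside partition-function
    recursions over the same structure ensemble as ``fold_mfe``.

    Partition weights are rescaled per nucleotide (as thermodynamic folders
    do) so that long, very stable windows do not overflow double precision.
    """
    arr = _encode(seq)
    n = len(arr)
    probs = np.zeros((n, n))
    if n < model.min_loop + 2:
        return probs
    beta = 1.0 / (GAS_CONSTANT * model.temperature)
    mfe, _ = fold_mfe(seq, model)
    # per-nucleotide scale factor; slightly over-scales to keep headroom
    sigma = math.exp(-beta * 1.05 * mfe / n) if mfe < 0 else 1.0
    pt = _PAIR_TYPE[arr[:, None], arr[None, :]]

    Qb = np.zeros((n, n))   # (i,j) paired, scaled by sigma^(span)
    Q1 = np.zeros((n + 2, n + 2))  # >=1 pair in [a,b]
    Q = np.zeros((n + 2, n + 2))   # all structures; empty region -> 1
    # inclusive [a,b]; treat b < a as empty with value 1 via helper

    def q(a, b):
        return 1.0 if b < a else Q[a, b]

    for span in range(0, n):
        for a in range(0, n - span):
            b = a + span
            # Qb for (a,b)
            p = pt[a, b]
            if p >= 0 and span >= model.min_loop + 1:
                total = math.exp(-beta * model.hairpin_penalty(b - a - 1)) \
                    * sigma ** (-(span + 1))
                ip = pt[a + 1, b - 1]
                if ip >= 0 and (b - 1) - (a + 1) - 1 >= model.min_loop:
                    total += math.exp(-beta * model.stack_energy(p, ip)) \
                        * Qb[a + 1, b - 1] * sigma ** (-2)
                if b - 1 >= a + 1:
                    total += (Q1[a + 1, b - 1] - Qb[a + 1, b - 1]) * sigma ** (-2)
                Qb[a, b] = total
            # Q / Q1 for [a,b]
            qv = q(a + 1, b) / sigma
            q1v = (Q1[a + 1, b] / sigma) if b >= a + 1 else 0.0
            ks = np.arange(a + model.min_loop + 1, b + 1)
            if ks.size:
                paired = Qb[a, ks] * np.array([q(int(k) + 1, b) for k in ks])
                s = float(paired.sum())
                qv += s
                q1v += s
            Q[a, b] = qv
            Q1[a, b] = q1v

    Zhat = Q[0, n - 1]
    if Zhat <= 0:
        return probs

    # outside recursion, decreasing span
    O = np.zeros((n, n))
    spans = sorted(
        ((i, j) for i in range(n) for j in range(i + model.min_loop + 1, n)
         if pt[i, j] >= 0 and Qb[i, j] > 0),
        key=lambda ij: ij[1] - ij[0], reverse=True)
    inv_sigma2 = sigma ** (-2)
    for i, j in spans:
        total = q(0, i - 1) * q(j + 1, n - 1)
        if i >= 1 and j <= n - 2:
            u = np.array([q(k + 1, i - 1) for k in range(0, i)])
            v = np.array([q(j + 1, l - 1) for l in range(j + 1, n)])
            total += float(u @ O[0:i, j + 1:n] @ v) * inv_sigma2
            ok, ol = i - 1, j + 1
            if pt[ok, ol] >= 0 and O[ok, ol] > 0:
                s = math.exp(-beta * model.stack_energy(pt[ok, ol], pt[i, j]))
                total += (s - 1.0) * O[ok, ol] * inv_sigma2
        O[i, j] = total
        probs[i, j] = Qb[i, j] * total / Zhat
    np.clip(probs, 0.0, 1.0, out=probs)
    return probs


def ensemble_free_energy(seq: str, model: EnergyModel = DEFAULT_MODEL) -> float:
    """-RT ln Z over the nested-structure ensemble (always <= MFE)."""
    arr = _encode(seq)
    n = len(arr)
    if n < model.min_loop + 2:
        return 0.0
    beta = 1.0 / (GAS_CONSTANT * model.temperature)
    mfe, _ = fold_mfe(seq, model)
    sigma = math.exp(-beta * 1.05 * mfe / n) if mfe < 0 else 1.0
    # recompute inside-only tables (cheap) to read off Z
    probs_unused = None
    # reuse partition recursion by inlining the inside part
    pt = _PAIR_TYPE[arr[:, None], arr[None, :]]
    Qb = np.zeros((n, n))
    Q1 = np.zeros((n + 2, n + 2))
    Q = np.zeros((n + 2, n + 2))

    def q(a, b):
        return 1.0 if b < a else Q[a, b]

    for span in range(0, n):
        for a in range(0, n - span):
            b = a + span
            p = pt[a, b]
            if p >= 0 and span >= model.min_loop + 1:
                total = math.exp(-beta * model.hairpin_penalty(b - a - 1)) \
                    * sigma ** (-(span + 1))
                ip = pt[a + 1, b - 1]
                if ip >= 0 and (b - 1) - (a + 1) - 1 >= model.min_loop:
                    total += math.exp(-beta * model.stack_energy(p, ip)) \
                        * Qb[a + 1, b - 1] * sigma ** (-2)
                if b - 1 >= a + 1:
                    total += (Q1[a + 1, b - 1] - Qb[a + 1, b - 1]) * sigma ** (-2)
                Qb[a, b] = total
            qv = q(a + 1, b) / sigma
            q1v = (Q1[a + 1, b] / sigma) if b >= a + 1 else 0.0
            ks = np.arange(a + model.min_loop + 1, b + 1)
            if ks.size:
                paired = Qb[a, ks] * np.array([q(int(k) + 1, b) for k in ks])
                s = float(paired.sum())
                qv += s
                q1v += s
            Q[a, b] = qv
            Q1[a, b] = q1v
    lnZ = math.log(Q[0, n - 1]) + n * math.log(sigma)
    return -lnZ / beta


def ensemble_diversity(bp_probs: np.ndarray) -> float:
    """Expected base-pair distance between two independent Boltzmann draws:
    ED = 2 * sum_{i<j} p(i,j) * (1 - p(i,j))."""
    upper = np.triu(bp_probs, k=1)
    return float(2.0 * np.sum(upper * (1.0 - upper)))


# ---------------------------------------------------------------------------
# fold engines (builtin + external plug-in)
# ---------------------------------------------------------------------------

class BuiltinFoldEngine:
    """Folds with the package's own DP + partition recursions."""

    name = "builtin"

    def __init__(self, model: EnergyModel = DEFAULT_MODEL):
        self.model = model

    def fold(self, seq: str) -> tuple[float, str, float]:
        mfe, db = fold_mfe(seq, self.model)
        ed = ensemble_diversity(partition_bp_probs(seq, self.model))
        return mfe, db, ed


class ExternalFoldEngine:
    """Plug-in contract for substituting a full thermodynamic folder.

    The command receives FASTA on stdin and must print one tab-separated
    line per record: ``id  energy  dot-bracket  ensemble_diversity``.
    """

    def __init__(self, command: str):
        self.command = command
        self.name = f"external:{shlex.split(command)[0]}"

    def fold(self, seq: str) -> tuple[float, str, float]:
        proc = subprocess.run(
            shlex.split(self.command), input=f">seq\n{seq}\n",
            capture_output=True, text=True, check=True)
        line = proc.stdout.strip().splitlines()[0]
        _, energy, db, ed = line.split("\t")
        return float(energy), db, float(ed)


def score_candidates(cands: list[PrecursorCandidate],
                     engine=None) -> list[PrecursorCandidate]:
    """Fill mfe/structure/ED for each precursor candidate."""
    engine = engine or BuiltinFoldEngine()
    out = []
    for c in cands:
        mfe, db, ed = engine.fold(c.precursor_seq)
        out.append(replace_fields(c, mfe=mfe, structure=db,
                                  ensemble_diversity=ed, engine=engine.name))
    return out


def replace_fields(c: PrecursorCandidate, **kw) -> PrecursorCandidate:
    d = dict(c.__dict__)
    d.update(kw)
    return PrecursorCandidate(**d)


# ---------------------------------------------------------------------------
# stage 4: filtering and reporting
# ---------------------------------------------------------------------------

REPORT_COLUMNS = ["mirna", "sequence", "length", "mismatch", "mfe", "ed"]


def apply_report_filters(
    report: pd.DataFrame,
    min_len: int = 18,
    max_mismatch: int = 2,
    mfe_max: float = -20.0,
    ed_threshold: float = 15.0,
    ed_direction: str = "le",
) -> pd.Series:
    """Boolean retention mask over a report table with length / mismatch /
    mfe / ed columns.  ``ed_direction`` selects ED <= or ED >= threshold."""
    if ed_direction not in ("le", "ge"):
        raise ValueError("ed_direction must be 'le' or 'ge'")
    mask = (report["length"] >= min_len) & (report["mismatch"] <= max_mismatch) \
        & (report["mfe"] <= mfe_max)
    if ed_direction == "le":
        mask &= report["ed"] <= ed_threshold
    else:
        mask &= report["ed"] >= ed_threshold
    return mask


def candidate_names(cands: list[PrecursorCandidate], prefix: str = "dro-") -> list[str]:
    """Name candidates after their matched mature, prefixing the species tag
    and suffixing duplicates with letters (name, nameb, namec, ...)."""
    seen: dict[str, int] = {}
    names = []
    for c in cands:
        base = prefix + c.hit.mature_id
        k = seen.get(base, 0)
        names.append(base if k == 0 else base + "abcdefghijklmnopqrstuvwxyz"[k])
        seen[base] = k + 1
    return names


def filter_candidates(
    cands: list[PrecursorCandidate],
    mfe_max: float = -20.0,
    ed_threshold: float = 15.0,
    ed_direction: str = "le",
    min_len: int = 18,
    max_mismatch: int = 2,
    name_prefix: str = "dro-",
    ncrnas: dict[str, str] | None = None,
) -> tuple[list[PrecursorCandidate], pd.DataFrame]:
    """Apply the discovery thresholds to scored candidates.

    Returns the retained candidates and a report table (miRNA, sequence,
    length, mismatch, MFE, ED) for the retained set.  Sequences in the
    report are the matched mature regions in DNA alphabet, mirroring the
    usual reporting convention.
    """
    names = candidate_names(cands, name_prefix)
    rows = []
    retained = []
    for name, c in zip(names, cands):
        if c.mfe is None or c.ensemble_diversity is None:
            raise ValueError("candidates must be scored before filtering")
        rel = c.hit.start - c.window_start
        mature_seq = c.precursor_seq[rel:rel + c.hit.length].replace("U", "T")
        row = {"mirna": name, "sequence": mature_seq, "length": c.hit.length,
               "mismatch": c.hit.mismatches, "mfe": c.mfe,
               "ed": c.ensemble_diversity}
        keep = bool(apply_report_filters(
            pd.DataFrame([row]), min_len, max_mismatch, mfe_max,
            ed_threshold, ed_direction).iloc[0])
        c2 = replace_fields(c, pass_mfe=c.mfe <= mfe_max,
                            pass_ed=(c.ensemble_diversity <= ed_threshold
                                     if ed_direction == "le"
                                     else c.ensemble_diversity >= ed_threshold))
        if keep:
            retained.append(c2)
            rows.append(row)
    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    return retained, report


@dataclass
class DiscoveryResult:
    """All intermediate stages of one discovery run.

    ``scored`` holds every scanned candidate with its thermodynamic
    descriptors; ``structural`` is the subset passing the scan + MFE
    criteria (the planted-recovery measure for synthetic corpora, where
    the hairpin stem controls MFE directly); ``retained``/``report`` add
    the ensemble-diversity cut on top.
    """

    hits: list
    scored: list
    structural: list
    retained: list
    report: pd.DataFrame


def discover(
    ncrnas: dict[str, str],
    mature_reference: dict[str, str],
    min_len: int = 18,
    max_mismatch: int = 2,
    flank: int = 50,
    mfe_max: float = -20.0,
    ed_threshold: float = 15.0,
    ed_direction: str = "le",
    engine=None,
) -> DiscoveryResult:
    """Run the full discovery pipeline: scan -> extract -> fold -> filter."""
    hits = scan_matches(ncrnas, mature_reference, min_len, max_mismatch)
    cands = [extract_precursor(ncrnas[h.ncrna_id], h, flank) for h in hits]
    cands = score_candidates(cands, engine)
    structural = [c for c in cands if c.mfe <= mfe_max]
    retained, report = filter_candidates(cands, mfe_max, ed_threshold,
                                         ed_direction, min_len, max_mismatch)
    return DiscoveryResult(hits, cands, structural, retained, report)
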