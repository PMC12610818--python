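"""Independent brute-force oracles used by the test suite.

Everything here is written from the definitions, not from the package's
algorithms: structure enumeration for folding thermodynamics, exhaustive
substring alignment for local scores, definitional graph-entropy
recomputation, and exact hypergeometric tail sums.
"""

from __future__ import annotations

import math
from math import comb

import numpy as np

WC = {"AU", "UA", "CG", "GC", "GU", "UG"}


def enumerate_structures(seq: str, min_loop: int = 3):
    """Yield every nested pair set (frozenset of (i, j)) with hairpin loops
    of at least min_loop unpaired bases."""
    n = len(seq)

    def rec(positions):
        if not positions:
            yield frozenset()
            return
        i = positions[0]
        yield from rec(positions[1:])
        for j in positions[1:]:
            if j - i - 1 < min_loop or seq[i] + seq[j] not in WC:
                continue
            inside = tuple(p for p in positions[1:] if i < p < j)
            outside = tuple(p for p in positions[1:] if p > j)
            for s1 in rec(inside):
                for s2 in rec(outside):
                    yield s1 | s2 | {(i, j)}

    yield from rec(tuple(range(n)))


def score_structure(seq: str, pairs, model) -> float:
    """Definitional scoring: stacking for a pair directly enclosing another,
    hairpin penalty for a pair with an empty interior, zero otherwise."""
    from batmirnet.mirna import _PAIR_INDEX  # pair-type indexing only

    total = 0.0
    ps = set(pairs)
    for i, j in ps:
        outer = _PAIR_INDEX[seq[i] + seq[j]]
        if (i + 1, j - 1) in ps:
            inner = _PAIR_INDEX[seq[i + 1] + seq[j - 1]]
            total += float(model.stack[outer, inner])
        elif not any(i < a < b < j for a, b in ps):
            total += model.hairpin_penalty(j - i - 1)
    return total


def brute_thermo(seq: str, model):
    """MFE, base-pair probability matrix, ensemble diversity and partition
    function by full enumeration (practical for length <= 14)."""
    from batmirnet.mirna import GAS_CONSTANT

    beta = 1.0 / (GAS_CONSTANT * model.temperature)
    n = len(seq)
    mfe = 0.0
    Z = 0.0
    pm = np.zeros((n, n))
    pair_sets = []
    weights = []
    for s in enumerate_structures(seq, model.min_loop):
        E = score_structure(seq, s, model)
        mfe = min(mfe, E)
        w = math.exp(-beta * E)
        Z += w
        for i, j in s:
            pm[i, j] += w
        pair_sets.append(s)
        weights.append(w)
    pm /= Z
    # expected symmetric difference over the enumerated ensemble
    w = np.array(weights) / Z
    ed = 0.0
    for a, sa in enumerate(pair_sets):
        for b, sb in enumerate(pair_sets):
            ed += w[a] * w[b] * len(sa ^ sb)
    return mfe, pm, ed, Z


def gotoh_global(a: str, b: str, score, gap_open: float, gap_extend: float) -> float:
    """Global affine-gap alignment score; a gap of length L costs
    gap_open + (L-1) * gap_extend."""
    NEG = -1e9
    la, lb = len(a), len(b)
    M = np.full((la + 1, lb + 1), NEG)
    X = np.full((la + 1, lb + 1), NEG)  # gap in b (consume a)
    Y = np.full((la + 1, lb + 1), NEG)  # gap in a (consume b)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, lb + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = score(a[i - 1], b[j - 1])
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend)
    return float(max(M[la, lb], X[la, lb], Y[la, lb]))


def exhaustive_local(a: str, b: str, score, gap_open: float, gap_extend: float) -> float:
    """Best local score as the maximum global score over all substring
    pairs (including the empty alignment at 0)."""
    best = 0.0
    for i in range(len(a)):
        for k in range(i + 1, len(a) + 1):
            for j in range(len(b)):
                for l in range(j + 1, len(b) + 1):
                    best = max(best, gotoh_global(a[i:k], b[j:l], score,
                                                  gap_open, gap_extend))
    return best


def hamming_scan(ncrna: str, mature: str, max_mismatch: int):
    """All-offset ungapped scan: (start, mismatches) for every window."""
    s = ncrna.upper().replace("T", "U")
    m = mature.upper().replace("T", "U")
    L = len(m)
    out = []
    for i in range(len(s) - L + 1):
        mm = sum(1 for x, y in zip(s[i:i + L], m) if x != y)
        if mm <= max_mismatch:
            out.append((i, mm))
    return out


def collapse_overlaps(hits, length):
    """Reference implementation of the duplicate-hit rule: within each run
    of mutually overlapping windows keep (fewest mismatches, then leftmost)."""
    out = []
    cluster = []
    end = -1
    for s, m in hits:
        if cluster and s >= end:
            out.append(min((m, s) for s, m in cluster))
            cluster = []
        cluster.append((s, m))
        end = s + length
    if cluster:
        out.append(min((m, s) for s, m in cluster))
    return [(s, m) for m, s in out]


def degree_entropy(graph, log=math.log) -> float:
    """Entropy straight from the definition."""
    from collections import Counter

    N = graph.number_of_nodes()
    counts = Counter(d for _, d in graph.degree())
    return -sum((c / N) * log(c / N) for c in counts.values())


def brute_knockout(graph, node, log=math.log) -> float:
    """Definitional entropy change: rebuild the reduced graph and reapply
    the degree-distribution formulas."""
    h0 = degree_entropy(graph, log)
    g = graph.copy()
    g.remove_node(node)
    return degree_entropy(g, log) - h0


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n) by exact summation."""
    denom = comb(N, n)
    return sum(comb(K, x) * comb(N - K, n - x)
               for x in range(k, min(K, n) + 1)) / denom
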