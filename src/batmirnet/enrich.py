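"""Gene-set enrichment (EASE-style modified Fisher test) and genomic-feature
comparisons for miRNA target sets.

The enrichment statistic is the conservative EASE variant of the one-sided
Fisher/hypergeometric test: the observed overlap is decremented by one
before computing the upper-tail probability, so single-gene overlaps can
never reach significance.  Feature comparisons contrast a target gene set
against the genomic background with a Welch two-sample t-test on raw values
and a chi-square test on counts over background-decile bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

FEATURES = ["cds_length", "transcript_length", "genome_span",
            "utr3_length", "gc_content", "exon_count"]


@dataclass(frozen=True)
class EnrichmentRow:
    category: str
    term: str
    count: int
    percent: float
    p_value: float
    p_adjusted: float


@dataclass(frozen=True)
class FeatureComparison:
    feature: str
    target_mean: float
    background_mean: float
    t_statistic: float | None
    p_t: float | None
    chi2_statistic: float
    p_chi: float
    direction: int  # sign of target mean - background mean
    note: str = ""


def ease_test(overlap: int, list_size: int, term_size: int, universe: int) -> float:
    """EASE score: one-sided hypergeometric upper tail with the overlap
    decremented by one (floored at zero); overlap of 0 or 1 gives p = 1."""
    k, n, K, N = overlap, list_size, term_size, universe
    if not (0 <= k <= min(n, K) <= N) or n < 1 or K < 1:
        raise ValueError("inconsistent contingency margins")
    kd = max(k - 1, 0)
    if kd == 0:
        return 1.0
    # P(X >= kd) for X ~ Hypergeom(N, K, n)
    return float(stats.hypergeom.sf(kd - 1, N, K, n))


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(ranked, 0.0, 1.0)
    return out


def enrich(
    gene_list: list[str],
    annotation: pd.DataFrame,
    universe: list[str],
    min_count: int = 2,
) -> list[EnrichmentRow]:
    """Per-term EASE enrichment of a gene list against a universe.

    ``annotation`` has columns (gene, category, term).  The percent column
    uses as denominator the number of list genes carrying at least one
    annotation in that category (logged).  BH adjustment is computed within
    each category; rows are sorted by ascending p.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    listed = set(gene_list)
    if not listed <= uni:
        raise ValueError("gene_list must be a subset of the universe")
    ann = annotation[annotation["gene"].isin(uni)]
    rows = []
    for category, sub in ann.groupby("category"):
        denom = sub[sub["gene"].isin(listed)]["gene"].nunique()
        logger.info("category %s: %d annotated list genes as percent denominator",
                    category, denom)
        cat_rows = []
        for term, genes in sub.groupby("term")["gene"]:
            term_genes = set(genes)
            k = len(term_genes & listed)
            if k < min_count:
                continue
            p = ease_test(k, len(listed), len(term_genes), len(uni))
            cat_rows.append((category, term, k,
                             100.0 * k / denom if denom else 0.0, p))
        if not cat_rows:
            continue
        padj = benjamini_hochberg(np.array([r[4] for r in cat_rows]))
        rows.extend(EnrichmentRow(*r, p_adjusted=float(a))
                    for r, a in zip(cat_rows, padj))
    rows.sort(key=lambda r: (r.p_value, r.category, r.term))
    return rows


def enrichment_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows],
                        columns=["category", "term", "count", "percent",
                                 "p_value", "p_adjusted"])


def feature_compare(
    target_ids: list[str],
    feature_table: pd.DataFrame,
    bins: int = 10,
    features: list[str] | None = None,
) -> list[FeatureComparison]:
    """Compare a target gene set against the genomic background feature by
    feature: Welch t on raw values, chi-square on target counts over
    background-quantile bins (expected uniform).

    ``feature_table`` is indexed by gene id (or has a ``gene`` column) with
    one numeric column per feature.  Genes in ``target_ids`` form the target
    group; all remaining rows are the background.
    """
    tbl = feature_table.set_index("gene") if "gene" in feature_table.columns else feature_table
    features = features or [f for f in FEATURES if f in tbl.columns]
    target_ids = list(target_ids)
    missing = set(target_ids) - set(tbl.index)
    if missing:
        raise ValueError(f"target ids absent from feature table: {sorted(missing)[:5]}")
    tmask = tbl.index.isin(target_ids)
    if tmask.sum() < 2 or (~tmask).sum() < 2:
        raise ValueError("need at least two genes per group")
    out = []
    for feat in features:
        x = tbl.loc[tmask, feat].to_numpy(dtype=float)
        y = tbl.loc[~tmask, feat].to_numpy(dtype=float)
        direction = int(np.sign(x.mean() - y.mean()))
        note = ""
        if np.var(x) == 0 or np.var(y) == 0:
            t_stat, p_t = None, None
            note = "t-test skipped: zero variance"
            logger.info("%s: %s", feat, note)
        else:
            t_stat, p_t = stats.ttest_ind(x, y, equal_var=False)
            t_stat, p_t = float(t_stat), float(p_t)
        # decile bins from the background distribution; rank-based, so any
        # strictly monotone transform of the feature leaves chi2 unchanged
        edges = np.quantile(y, np.linspace(0, 1, bins + 1)[1:-1])
        obs = np.bincount(np.searchsorted(edges, x, side="right"), minlength=bins)
        expected = np.full(bins, len(x) / bins)
        chi2, p_chi = stats.chisquare(obs, expected)
        out.append(FeatureComparison(
            feature=feat, target_mean=float(x.mean()),
            background_mean=float(y.mean()), t_statistic=t_stat, p_t=p_t,
            chi2_statistic=float(chi2), p_chi=float(p_chi),
            direction=direction, note=note))
    return out


def feature_frame(comparisons: list[FeatureComparison]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in comparisons])
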