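"""Contingency statistics: per-term Fisher/hypergeometric enrichment,
subset-proportion chi-square, and Benjamini–Hochberg adjustment.

The enrichment p-value is the one-sided (over-representation) Fisher
exact probability, i.e. the upper hypergeometric tail P(X >= k) for k
successes among n draws from a universe of N with K marked. Fold
enrichment is (k / n_affected) / ((K - k) / n_background) — the observed
rate among affected genes over the rate among non-affected genes — which
is +inf exactly when every gene carrying the term is affected (K = k > 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "EnrichmentRow",
    "fisher_domain_enrichment",
    "geneset_enrichment",
    "subset_proportion_test",
    "bh_adjust",
]


@dataclass(frozen=True)
class EnrichmentRow:
    term: str
    k: int  # affected genes carrying the term
    K: int  # all genes carrying the term
    n_affected: int
    n_background: int
    p: float
    p_adj: float
    fold: float
    significant: Optional[bool] = None


def _hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n)."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def _fold(k: int, K: int, n_affected: int, n_background: int) -> float:
    if k == 0:
        return 0.0
    if K == k:
        return float("inf")
    return (k / n_affected) / ((K - k) / n_background)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone,
    order-preserving, capped at 1)."""
    return stats.false_discovery_control(np.asarray(p_values, dtype=float),
                                         method="bh")


def fisher_domain_enrichment(affected: set, background: set,
                             domain_map: dict) -> list:
    """Per-domain one-sided Fisher exact tests of the affected gene set
    against the background, BH-adjusted across all tested domains.

    ``domain_map`` maps term -> set of genes carrying that term; genes
    outside affected|background are ignored; terms with no gene in the
    universe are skipped.
    """
    affected = set(affected)
    background = set(background)
    if affected & background:
        raise ValueError("affected and background sets must be disjoint")
    universe = affected | background
    n_affected, n_background = len(affected), len(background)
    N = n_affected + n_background
    rows = []
    for term in sorted(domain_map):
        genes = set(domain_map[term]) & universe
        K = len(genes)
        if K == 0:
            continue
        k = len(genes & affected)
        p = _hypergeom_upper_tail(k, N, K, n_affected)
        rows.append((term, k, K, p))
    if not rows:
        return []
    p_adj = bh_adjust([r[3] for r in rows])
    return [
        EnrichmentRow(term=term, k=k, K=K, n_affected=n_affected,
                      n_background=n_background, p=p, p_adj=float(q),
                      fold=_fold(k, K, n_affected, n_background))
        for (term, k, K, p), q in zip(rows, p_adj)
    ]


def geneset_enrichment(genes: set, universe: set, term_map: dict,
                       p_threshold: float = 0.05,
                       q_threshold: float = 0.05) -> list:
    """Generic hypergeometric over-representation of a gene set against
    a supplied universe, BH-adjusted; rows are flagged significant when
    both raw p and adjusted p pass their thresholds."""
    genes = set(genes)
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    if not genes <= universe:
        raise ValueError("query genes must be a subset of the universe")
    N, n = len(universe), len(genes)
    rows = []
    for term in sorted(term_map):
        term_genes = set(term_map[term]) & universe
        K = len(term_genes)
        if K == 0:
            continue
        k = len(term_genes & genes)
        p = _hypergeom_upper_tail(k, N, K, n)
        rows.append((term, k, K, p))
    if not rows:
        return []
    p_adj = bh_adjust([r[3] for r in rows])
    return [
        EnrichmentRow(term=term, k=k, K=K, n_affected=n,
                      n_background=N - n, p=p, p_adj=float(q),
                      fold=_fold(k, K, n, N - n),
                      significant=bool(p < p_threshold and q < q_threshold))
        for (term, k, K, p), q in zip(rows, p_adj)
    ]


@dataclass(frozen=True)
class ProportionTestResult:
    statistic: float
    p: float
    prop_subset: float
    prop_complement: float
    prop_all: float
    reliable: bool  # False when an expected cell count is below 1


def subset_proportion_test(k_sub: int, n_sub: int,
                           k_all: int, n_all: int) -> ProportionTestResult:
    """Pearson chi-square (df=1, no continuity correction) comparing a
    subset's success proportion against its complement.

    The 2x2 table is [[k_sub, n_sub - k_sub],
                      [k_all - k_sub, (n_all - n_sub) - (k_all - k_sub)]].
    """
    if not (0 <= k_sub <= n_sub <= n_all and k_sub <= k_all <= n_all):
        raise ValueError("inconsistent subset counts")
    a = k_sub
    b = n_sub - k_sub
    c = k_all - k_sub
    d = (n_all - n_sub) - (k_all - k_sub)
    table = np.array([[a, b], [c, d]], dtype=float)
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    reliable = bool(expected.min() >= 1)
    if np.any(expected == 0):
        stat, p = 0.0, 1.0
    else:
        stat = float(((table - expected) ** 2 / expected).sum())
        p = float(stats.chi2.sf(stat, df=1))
    return ProportionTestResult(
        statistic=stat, p=p,
        prop_subset=k_sub / n_sub if n_sub else float("nan"),
        prop_complement=c / (n_all - n_sub) if n_all > n_sub else float("nan"),
        prop_all=k_all / n_all,
        reliable=reliable,
    )
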