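"""Allele statistics, Weir–Cockerham F_ST, SV density and genotype PCA.

F_ST is the per-site Weir & Cockerham (1984) estimator for diploids,
computed from the variance components a (among populations), b (among
individuals within populations) and c (within individuals):
theta = a / (a + b + c). Per-site values are the unit statistic consumed
by the domestication scan; the ratio-of-averages sum(a)/sum(a+b+c) is
reported as a diagnostic. Negative per-site values are retained (they
carry ranking information); sites where a+b+c = 0 are undefined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import Genotype, PopulationPanel, SVRecord

__all__ = [
    "AlleleStats",
    "FSTResult",
    "DensityWindow",
    "allele_stats",
    "genotype_matrix",
    "wc_fst",
    "wc_fst_table",
    "fst_ratio_of_averages",
    "sv_density",
    "size_maf_summaries",
    "genotype_pca",
]


@dataclass(frozen=True)
class AlleleStats:
    af: float
    maf: float
    ac: int
    an: int
    call_rate: float
    defined: bool = True


@dataclass(frozen=True)
class FSTResult:
    sv_id: str
    comparison: str
    a: float
    b: float
    c: float
    theta: Optional[float]  # None when a+b+c == 0
    delta_af: float


@dataclass(frozen=True)
class DensityWindow:
    chrom: str
    start: int
    end: int
    count: int
    klass: str  # HIGH / LOW / NORMAL
    partial: bool = False


def genotype_matrix(records: Sequence[SVRecord]) -> np.ndarray:
    """(n_records, n_samples) int8 matrix of genotype codes."""
    return np.vstack([r.genotypes for r in records])


def allele_stats(record: SVRecord, subset: Optional[np.ndarray] = None) -> AlleleStats:
    """ALT allele statistics over non-missing genotypes of a sample
    subset (indices into the roster; None = all samples)."""
    g = record.genotypes if subset is None else record.genotypes[subset]
    if g.size == 0:
        raise ValueError("empty sample subset")
    called = g != Genotype.MISSING
    n_called = int(called.sum())
    if n_called == 0:
        return AlleleStats(np.nan, np.nan, 0, 0, 0.0, defined=False)
    ac = int(np.sum(g == Genotype.HET) + 2 * np.sum(g == Genotype.HOM_ALT))
    an = 2 * n_called
    af = ac / an
    return AlleleStats(af=af, maf=min(af, 1 - af), ac=ac, an=an,
                       call_rate=n_called / g.size)


def _group_summaries(G: np.ndarray, idx: np.ndarray) -> tuple:
    """Per-site (n called, alt freq, observed het freq) for one group.

    G is (n_sites, n_samples) of genotype codes.
    """
    sub = G[:, idx]
    called = sub != Genotype.MISSING
    n = called.sum(axis=1).astype(float)
    het = (sub == Genotype.HET).sum(axis=1).astype(float)
    ac = het + 2 * (sub == Genotype.HOM_ALT).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, ac / (2 * n), np.nan)
        h = np.where(n > 0, het / n, np.nan)
    return n, p, h


def _wc_components(n1, p1, h1, n2, p2, h2) -> tuple:
    """Weir & Cockerham (1984) two-population variance components,
    vectorized over sites. Returns (a, b, c, valid)."""
    r = 2.0
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    valid = (n1 >= 2) & (n2 >= 2)
    n_bar = (n1 + n2) / r
    n_total = n1 + n2
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = (n_total - (n1 ** 2 + n2 ** 2) / n_total) / (r - 1)
        p_bar = (n1 * p1 + n2 * p2) / n_total
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / n_total
        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - (r - 1) / r * s2
            - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2
    return a, b, c, valid


def wc_fst(record: SVRecord, panel: PopulationPanel, roster: Sequence[str],
           group1: str, group2: str) -> FSTResult:
    """Per-site Weir–Cockerham theta for one record and one pair of
    groups; delta_af is af(group1) - af(group2) over called genotypes."""
    table = wc_fst_table([record], panel, roster, [(group1, group2)])
    row = table.iloc[0]
    theta = None if not np.isfinite(row["theta"]) else float(row["theta"])
    return FSTResult(sv_id=record.id, comparison=row["comparison"],
                     a=float(row["a"]), b=float(row["b"]), c=float(row["c"]),
                     theta=theta, delta_af=float(row["delta_af"]))


def wc_fst_table(records: Sequence[SVRecord], panel: PopulationPanel,
                 roster: Sequence[str], comparisons: Sequence[tuple]) -> pd.DataFrame:
    """Per-site theta for every record x comparison.

    Columns: sv_id, comparison ("G1_vs_G2"), a, b, c, theta (NaN when
    undefined), delta_af, defined. Samples in the panel's exclusion set
    never enter.
    """
    G = genotype_matrix(records)
    ids = [r.id for r in records]
    frames = []
    for g1, g2 in comparisons:
        idx1 = panel.indices_in(list(roster), g1)
        idx2 = panel.indices_in(list(roster), g2)
        if idx1.size == 0 or idx2.size == 0:
            raise ValueError(f"empty group in comparison {g1} vs {g2}")
        n1, p1, h1 = _group_summaries(G, idx1)
        n2, p2, h2 = _group_summaries(G, idx2)
        a, b, c, valid = _wc_components(n1, p1, h1, n2, p2, h2)
        denom = a + b + c
        with np.errstate(invalid="ignore", divide="ignore"):
            theta = np.where(valid & (denom != 0), a / denom, np.nan)
        frames.append(pd.DataFrame({
            "sv_id": ids,
            "comparison": f"{g1}_vs_{g2}",
            "a": np.where(valid, a, np.nan),
            "b": np.where(valid, b, np.nan),
            "c": np.where(valid, c, np.nan),
            "theta": theta,
            "delta_af": p1 - p2,
            "defined": valid & (denom != 0),
        }))
    return pd.concat(frames, ignore_index=True)


def fst_ratio_of_averages(table: pd.DataFrame, comparison: Optional[str] = None) -> float:
    """sum(a) / sum(a+b+c) over defined sites — the multi-locus
    (ratio-of-averages) estimate, reported for diagnostics."""
    t = table if comparison is None else table[table["comparison"] == comparison]
    t = t[t["defined"]]
    denom = (t["a"] + t["b"] + t["c"]).sum()
    return float(t["a"].sum() / denom)


def sv_density(records: Sequence[SVRecord], chrom_lengths: dict,
               window_bp: int = 1_000_000, high: int = 80, low: int = 10) -> list:
    """SV counts on a fixed window grid; each SV is assigned to the
    window containing its start. Classes are strict: HIGH when count >
    high, LOW when count < low. Trailing partial windows are flagged."""
    counts: dict = {}
    for rec in records:
        if rec.chrom not in chrom_lengths:
            raise KeyError(f"chromosome {rec.chrom} missing from chrom_lengths")
        counts[(rec.chrom, rec.start // window_bp)] = \
            counts.get((rec.chrom, rec.start // window_bp), 0) + 1
    windows: list = []
    for chrom, length in chrom_lengths.items():
        n_windows = (length + window_bp - 1) // window_bp
        for w in range(n_windows):
            start = w * window_bp
            end = min(length, start + window_bp)
            c = counts.get((chrom, w), 0)
            klass = "HIGH" if c > high else ("LOW" if c < low else "NORMAL")
            windows.append(DensityWindow(chrom, start, end, c, klass,
                                         partial=end - start < window_bp))
    return windows


def size_maf_summaries(records: Sequence[SVRecord],
                       stats: Optional[Sequence[AlleleStats]] = None,
                       maf_rare: float = 0.05) -> dict:
    """Per-type size summaries plus dataset-wide MAF summaries.

    Size classes follow the conventional violin split [50, 1000) and
    [1000, 10000) bp; the 'fraction below 1.5 kb' headline and the count
    of rare sites (MAF < maf_rare) are included when stats are given.
    """
    per_type: dict = {}
    all_lengths = []
    for rec in records:
        if rec.length is None:
            continue
        per_type.setdefault(rec.svtype, []).append(rec.length)
        all_lengths.append(rec.length)
    type_summary = {}
    for svtype, lengths in per_type.items():
        arr = np.array(lengths)
        type_summary[svtype] = {
            "count": int(arr.size),
            "cumulative_bp": int(arr.sum()),
            "mean_length": float(arr.mean()),
            "median_length": float(np.median(arr)),
            "n_50_1000": int(np.sum((arr >= 50) & (arr < 1000))),
            "n_1000_10000": int(np.sum((arr >= 1000) & (arr < 10000))),
        }
    out: dict = {"per_type": type_summary}
    if all_lengths:
        arr = np.array(all_lengths)
        out["overall"] = {
            "count": int(arr.size),
            "cumulative_bp": int(arr.sum()),
            "mean_length": float(arr.mean()),
            "median_length": float(np.median(arr)),
            "fraction_below_1500bp": float(np.mean(arr < 1500)),
        }
    if stats is not None:
        mafs = np.array([s.maf for s in stats if s.defined])
        hist, edges = np.histogram(mafs, bins=np.arange(0, 0.55, 0.05))
        out["maf"] = {
            "n_defined": int(mafs.size),
            "n_rare": int(np.sum(mafs < maf_rare)),
            "histogram_counts": hist.tolist(),
            "histogram_edges": np.round(edges, 4).tolist(),
        }
    return out


def genotype_pca(records: Sequence[SVRecord], roster: Sequence[str],
                 n_components: int = 10, scale: bool = False) -> tuple:
    """PCA of the 0/1/2 genotype matrix (samples x SVs).

    Missing genotypes are imputed with the per-SV mean; columns are
    centered (and optionally scaled); components come from an SVD with a
    deterministic sign convention. Returns (coords DataFrame indexed by
    sample, explained_variance_ratio array).
    """
    n_samples = len(roster)
    if n_components > n_samples:
        raise ValueError("more components requested than samples")
    X = genotype_matrix(records).astype(float).T  # samples x svs
    X[X == Genotype.MISSING] = np.nan
    col_mean = np.nanmean(X, axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    nan_mask = np.isnan(X)
    X[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    X -= col_mean
    if scale:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X /= sd
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    k = min(n_components, S.size)
    # sign convention: largest-magnitude loading of each component positive
    for j in range(k):
        i_max = np.argmax(np.abs(Vt[j]))
        if Vt[j, i_max] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    coords = U[:, :k] * S[:k]
    total_var = (S ** 2).sum()
    evr = (S[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    df = pd.DataFrame(coords, index=list(roster),
                      columns=[f"PC{i + 1}" for i in range(k)])
    return df, evr
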