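"""Reciprocal-overlap joins and interval set operations.

The central operation, :func:`overlap_join`, mirrors the semantics of
``bedtools intersect -wo [-f F -r]``: a query/subject pair is reported
when the shared span reaches ``min_bp`` AND both overlap fractions reach
``min_recip`` (both thresholds inclusive, matching bedtools' ``>=``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

from .model import BedFeature, GenomicInterval, SVRecord

logger = logging.getLogger(__name__)

__all__ = [
    "OverlapPair",
    "overlap_join",
    "GerpOverlapSummary",
    "summarize_gerp_overlap",
    "find_redundant_svs",
    "merge_sv_sets",
]


@dataclass(frozen=True)
class OverlapPair:
    query_id: str
    subject_id: str
    chrom: str
    overlap_bp: int
    frac_query: float
    frac_subject: float


def _coerce(items: Sequence, prefix: str) -> list:
    """Normalize SVRecord / BedFeature / GenomicInterval inputs to
    (id, chrom, start, end) tuples, inventing positional ids if needed."""
    out = []
    for i, it in enumerate(items):
        if isinstance(it, SVRecord):
            out.append((it.id, it.chrom, it.start, it.end))
        elif isinstance(it, BedFeature):
            out.append((it.name if it.name is not None else f"{prefix}{i}",
                        it.chrom, it.start, it.end))
        elif isinstance(it, GenomicInterval):
            out.append((f"{prefix}{i}", it.chrom, it.start, it.end))
        else:  # (id, chrom, start, end) tuple
            out.append(tuple(it))
    return out


def overlap_join(queries: Sequence, subjects: Sequence,
                 min_bp: int = 1, min_recip: float = 0.0) -> list:
    """All query/subject pairs with overlap >= min_bp and reciprocal
    fraction >= min_recip (on both sides). Inputs need not be sorted."""
    qs = _coerce(queries, "q")
    ss = _coerce(subjects, "s")
    trees: dict = {}
    for sid, chrom, start, end in ss:
        trees.setdefault(chrom, IntervalTree()).addi(start, end, sid)
    pairs: list = []
    for qid, chrom, qstart, qend in qs:
        tree = trees.get(chrom)
        if tree is None:
            continue
        qlen = qend - qstart
        for hit in sorted(tree.overlap(qstart, qend)):
            ov = min(qend, hit.end) - max(qstart, hit.begin)
            if ov < min_bp:
                continue
            fq = ov / qlen
            fs = ov / (hit.end - hit.begin)
            if min(fq, fs) >= min_recip:
                pairs.append(OverlapPair(qid, hit.data, chrom, ov, fq, fs))
    return pairs


@dataclass
class GerpOverlapSummary:
    """Overlap of SVs with constrained elements plus global summaries.

    ``element_length_mean/sd`` summarise the lengths of every overlapped
    element (one entry per reported pair); ``overlap_mean/sd`` summarise
    the shared spans. SDs are population SDs (ddof=0) by default. All
    four are None when nothing overlaps — absent, not zero.
    """

    pairs: list
    per_sv: dict  # sv_id -> list of OverlapPair
    n_svs_overlapping: int
    n_elements_overlapped: int
    element_length_mean: Optional[float]
    element_length_sd: Optional[float]
    overlap_mean: Optional[float]
    overlap_sd: Optional[float]


def summarize_gerp_overlap(svs: Sequence, elements: Sequence,
                           min_bp: int = 1, ddof: int = 0) -> GerpOverlapSummary:
    """>=1 bp overlap of SVs with constrained elements, with the
    mean/SD of overlapped-element lengths and of overlap lengths."""
    elems = _coerce(elements, "e")
    lengths = {eid: end - start for eid, _, start, end in elems}
    pairs = overlap_join(svs, elems, min_bp=min_bp, min_recip=0.0)
    per_sv: dict = {}
    for p in pairs:
        per_sv.setdefault(p.query_id, []).append(p)
    if not pairs:
        return GerpOverlapSummary(pairs, per_sv, 0, 0, None, None, None, None)
    elem_lengths = np.array([lengths[p.subject_id] for p in pairs], dtype=float)
    ov_lengths = np.array([p.overlap_bp for p in pairs], dtype=float)
    return GerpOverlapSummary(
        pairs=pairs,
        per_sv=per_sv,
        n_svs_overlapping=len(per_sv),
        n_elements_overlapped=len({p.subject_id for p in pairs}),
        element_length_mean=float(elem_lengths.mean()),
        element_length_sd=float(elem_lengths.std(ddof=ddof)),
        overlap_mean=float(ov_lengths.mean()),
        overlap_sd=float(ov_lengths.std(ddof=ddof)),
    )


class _UnionFind:
    def __init__(self, items: Iterable):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


@dataclass
class RedundancyCluster:
    svtype: str
    member_ids: list
    start_spread: int  # max - min start among members
    end_spread: int


def find_redundant_svs(records: Sequence[SVRecord],
                       min_recip: float = 0.95) -> list:
    """Single-linkage clusters of same-type records whose pairwise
    reciprocal overlap strictly exceeds ``min_recip`` — likely duplicate
    calls of one underlying variant. Singleton clusters are not reported."""
    by_type: dict = {}
    for rec in records:
        if rec.svtype != "BND":
            by_type.setdefault(rec.svtype, []).append(rec)
    clusters: list = []
    for svtype, recs in by_type.items():
        uf = _UnionFind([r.id for r in recs])
        pairs = overlap_join(recs, recs, min_bp=1, min_recip=0.0)
        for p in pairs:
            if p.query_id >= p.subject_id:
                continue
            if min(p.frac_query, p.frac_subject) > min_recip:
                uf.union(p.query_id, p.subject_id)
        groups: dict = {}
        for r in recs:
            groups.setdefault(uf.find(r.id), []).append(r)
        for members in groups.values():
            if len(members) < 2:
                continue
            starts = [m.start for m in members]
            ends = [m.end for m in members]
            clusters.append(RedundancyCluster(
                svtype=svtype,
                member_ids=sorted(m.id for m in members),
                start_spread=max(starts) - min(starts),
                end_spread=max(ends) - min(ends),
            ))
    clusters.sort(key=lambda c: (c.svtype, c.member_ids))
    return clusters


@dataclass
class MergeResult:
    retained: list  # combined-call records matching either source set
    frac_a_captured: float
    frac_b_captured: float
    n_multi_matched: int  # combined records matching >1 source record


def merge_sv_sets(set_a: Sequence[SVRecord], set_b: Sequence[SVRecord],
                  combined_calls: Sequence[SVRecord]) -> MergeResult:
    """Keep combined-cohort records matching a record of either source
    set at 100% reciprocal overlap — i.e. identical chrom/start/end (and
    SVTYPE). Returns the retained set plus the fraction of each source
    set captured."""
    def keyset(recs):
        return {(r.chrom, r.start, r.end, r.svtype) for r in recs}

    keys_a, keys_b = keyset(set_a), keyset(set_b)
    key_counts: dict = {}
    retained = []
    for rec in combined_calls:
        key = (rec.chrom, rec.start, rec.end, rec.svtype)
        if key in keys_a or key in keys_b:
            retained.append(rec)
            key_counts[key] = key_counts.get(key, 0) + 1
    n_multi = sum(1 for v in key_counts.values() if v > 1)
    if n_multi:
        logger.warning("%d coordinates matched by multiple combined records", n_multi)
    captured = set(key_counts)
    frac_a = len(keys_a & captured) / len(keys_a) if keys_a else 0.0
    frac_b = len(keys_b & captured) / len(keys_b) if keys_b else 0.0
    return MergeResult(retained, frac_a, frac_b, n_multi)
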