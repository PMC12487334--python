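"""Consequence annotation of structural variants against gene models.

A deliberately compact effect vocabulary in the style of SnpEff's SV
logic. The analyses downstream only depend on the HIGH / non-HIGH
partition and on the broad category groups, so the vocabulary covers the
disruptive events (whole-transcript ablation, exon loss, frameshift,
gene fusions), the moderate structural ones (exonic duplication,
whole-gene inversion), UTR/intronic placement, and proximity terms.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .model import GeneModel, Genotype, SVRecord

__all__ = [
    "SVAnnotation",
    "IMPACT_ORDER",
    "HIGH_IMPACT_TERMS",
    "TERM_IMPACT",
    "classify_sv",
    "annotate_all",
    "aggregate_gene_sets",
    "summarize_categories",
    "select_curation_samples",
]

IMPACT_ORDER = ("MODIFIER", "LOW", "MODERATE", "HIGH")

HIGH_IMPACT_TERMS = frozenset({
    "transcript_ablation",
    "exon_loss_variant",
    "frameshift_variant",
    "gene_fusion",
    "bidirectional_gene_fusion",
})

TERM_IMPACT = {
    "transcript_ablation": "HIGH",
    "exon_loss_variant": "HIGH",
    "frameshift_variant": "HIGH",
    "gene_fusion": "HIGH",
    "bidirectional_gene_fusion": "HIGH",
    "exon_region_variant": "MODERATE",
    "transcript_inversion": "MODERATE",
    "5_prime_UTR_variant": "LOW",
    "3_prime_UTR_variant": "LOW",
    "intron_variant": "MODIFIER",
    "gene_variant": "MODIFIER",
    "upstream_gene_variant": "MODIFIER",
    "downstream_gene_variant": "MODIFIER",
    "intergenic_region": "MODIFIER",
}


@dataclass(frozen=True)
class SVAnnotation:
    sv_id: str
    gene_id: Optional[str]  # None for intergenic
    consequence: str
    impact: str


def _bp_in(pos: int, start: int, end: int) -> bool:
    """Breakpoint base at `pos` lies within [start, end)."""
    return start <= pos < end


def _sv_breakpoint_bases(start: int, end: int) -> tuple:
    # the first and the last base the SV touches
    return start, end - 1


def _fully_inside_intron(sv: SVRecord, gene: GeneModel) -> bool:
    for tx in gene.transcripts:
        exons = tx.exons
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if e1 <= sv.start and sv.end <= s2:
                return True
    return False


def _cds_overlap_bp(sv: SVRecord, tx) -> int:
    total = 0
    for s, e in tx.cds:
        total += max(0, min(sv.end, e) - max(sv.start, s))
    return total


def _frameshift(sv: SVRecord, gene: GeneModel) -> bool:
    """DEL/DUP breakpoint strictly inside a CDS interval with the
    affected CDS length not a multiple of 3, per transcript."""
    if sv.svtype not in ("DEL", "DUP"):
        return False
    b1, b2 = _sv_breakpoint_bases(sv.start, sv.end)
    for tx in gene.transcripts:
        bp_in_cds = any(
            _bp_in(b, s, e) for b in (b1, b2) for s, e in tx.cds
        )
        if bp_in_cds and _cds_overlap_bp(sv, tx) % 3 != 0:
            return True
    return False


def _gene_level_terms(sv: SVRecord, gene: GeneModel) -> set:
    terms: set = set()
    b1, b2 = _sv_breakpoint_bases(sv.start, sv.end)
    sv_contains = lambda s, e: sv.start <= s and e <= sv.end

    if sv.svtype == "DEL":
        if any(sv_contains(*tx.span) for tx in gene.transcripts):
            terms.add("transcript_ablation")
        elif any(sv_contains(s, e) for tx in gene.transcripts for s, e in tx.exons):
            terms.add("exon_loss_variant")
    elif sv.svtype == "DUP":
        if any(sv_contains(s, e) for tx in gene.transcripts for s, e in tx.exons):
            terms.add("exon_region_variant")
    elif sv.svtype == "INV":
        if sv.start <= gene.start and gene.end <= sv.end:
            terms.add("transcript_inversion")

    if _frameshift(sv, gene):
        terms.add("frameshift_variant")

    for tx in gene.transcripts:
        for b in (b1, b2):
            if any(_bp_in(b, s, e) for s, e in tx.utr5):
                terms.add("5_prime_UTR_variant")
            if any(_bp_in(b, s, e) for s, e in tx.utr3):
                terms.add("3_prime_UTR_variant")

    if _fully_inside_intron(sv, gene):
        terms.add("intron_variant")
    return terms


def classify_sv(sv: SVRecord, gene_models: Sequence[GeneModel],
                updown_bp: int = 5000) -> list:
    """Annotate one SV against all gene models on its chromosome.

    Emits every applicable term per overlapping/nearby gene; the fusion
    terms fire when the SV leaves one breakpoint inside each of two
    distinct genes (same strand -> gene_fusion, opposite ->
    bidirectional_gene_fusion). An SV overlapping a gene without matching
    any specific rule gets the catch-all ``gene_variant`` so that every
    SV carries at least one annotation; an SV with no gene within
    ``updown_bp`` is ``intergenic_region``.
    """
    b1, b2 = _sv_breakpoint_bases(sv.start, sv.end)
    overlapping = [g for g in gene_models
                   if g.chrom == sv.chrom and sv.start < g.end and g.start < sv.end]
    # fusion detection: one breakpoint inside each of two distinct genes
    genes_b1 = [g for g in overlapping if _bp_in(b1, g.start, g.end)]
    genes_b2 = [g for g in overlapping if _bp_in(b2, g.start, g.end)]
    fusion_pairs = [(ga, gb) for ga in genes_b1 for gb in genes_b2
                    if ga.gene_id != gb.gene_id]

    per_gene: dict = {}
    for gene in overlapping:
        per_gene[gene.gene_id] = _gene_level_terms(sv, gene)
    for ga, gb in fusion_pairs:
        term = "gene_fusion" if ga.strand == gb.strand else "bidirectional_gene_fusion"
        per_gene[ga.gene_id].add(term)
        per_gene[gb.gene_id].add(term)
    for gene_id, terms in per_gene.items():
        if not terms:
            terms.add("gene_variant")

    annotations: list = []
    for gene in overlapping:
        for term in sorted(per_gene[gene.gene_id]):
            annotations.append(
                SVAnnotation(sv.id, gene.gene_id, term, TERM_IMPACT[term]))

    # proximity terms for non-overlapping genes within updown_bp; an SV
    # can be upstream of one gene and downstream of another
    nearby = []
    for g in gene_models:
        if g.chrom != sv.chrom or (sv.start < g.end and g.start < sv.end):
            continue
        gap = g.start - sv.end if g.start >= sv.end else sv.start - g.end
        if 0 <= gap <= updown_bp:
            nearby.append(g)
    for g in nearby:
        sv_before_gene = sv.end <= g.start
        if g.strand == "+":
            term = "upstream_gene_variant" if sv_before_gene else "downstream_gene_variant"
        else:
            term = "downstream_gene_variant" if sv_before_gene else "upstream_gene_variant"
        annotations.append(SVAnnotation(sv.id, g.gene_id, term, TERM_IMPACT[term]))

    if not annotations:
        annotations.append(
            SVAnnotation(sv.id, None, "intergenic_region", "MODIFIER"))
    return annotations


def annotate_all(records: Sequence[SVRecord], gene_models: Sequence[GeneModel],
                 updown_bp: int = 5000) -> list:
    by_chrom: dict = {}
    for g in gene_models:
        by_chrom.setdefault(g.chrom, []).append(g)
    out: list = []
    for rec in records:
        out.extend(classify_sv(rec, by_chrom.get(rec.chrom, []), updown_bp=updown_bp))
    return out


def aggregate_gene_sets(annotations: Sequence[SVAnnotation],
                        all_gene_ids: Sequence[str]) -> tuple:
    """(affected_high_impact, associated, background) gene sets.

    affected: genes with >= 1 HIGH annotation; associated: genes with any
    annotation (incl. up/downstream); background: all genes minus the
    affected set.
    """
    affected = {a.gene_id for a in annotations
                if a.impact == "HIGH" and a.gene_id is not None}
    associated = {a.gene_id for a in annotations if a.gene_id is not None}
    background = set(all_gene_ids) - affected
    return affected, associated, background


def summarize_categories(annotations: Sequence[SVAnnotation]) -> dict:
    """Per-term and per-impact proportions over all emitted annotations,
    plus the co-occurrence counts of term-sets per SV (UpSet-style)."""
    term_counts = Counter(a.consequence for a in annotations)
    impact_counts = Counter(a.impact for a in annotations)
    total = sum(term_counts.values())
    per_sv_terms: dict = {}
    for a in annotations:
        per_sv_terms.setdefault(a.sv_id, set()).add(a.consequence)
    cooccurrence = Counter(frozenset(v) for v in per_sv_terms.values())
    return {
        "term_counts": dict(term_counts),
        "term_proportions": {t: c / total for t, c in term_counts.items()} if total else {},
        "impact_proportions": {t: c / total for t, c in impact_counts.items()} if total else {},
        "cooccurrence": dict(cooccurrence),
        "n_annotations": total,
        "n_svs": len(per_sv_terms),
    }


def select_curation_samples(record: SVRecord, roster: Sequence[str],
                            seed: int) -> list:
    """Pick up to 7 samples for visual curation of one SV: when
    available, 2 homozygous-reference, 2 heterozygous and 3 homozygous-
    alternate samples (drawn without replacement); shortfalls in a class
    are back-filled at random from the remaining called samples. With
    fewer than 7 called samples, all of them are returned."""
    rng = np.random.default_rng(seed)
    g = record.genotypes
    called_idx = np.flatnonzero(g != Genotype.MISSING)
    if called_idx.size <= 7:
        return [roster[i] for i in called_idx]
    chosen: list = []
    for target_gt, quota in ((Genotype.HOM_REF, 2), (Genotype.HET, 2),
                             (Genotype.HOM_ALT, 3)):
        pool = np.flatnonzero(g == target_gt)
        take = min(quota, pool.size)
        if take:
            chosen.extend(rng.choice(pool, size=take, replace=False).tolist())
    shortfall = 7 - len(chosen)
    if shortfall > 0:
        remaining = np.setdiff1d(called_idx, np.array(chosen, dtype=int))
        take = min(shortfall, remaining.size)
        if take:
            chosen.extend(rng.choice(remaining, size=take, replace=False).tolist())
    return [roster[i] for i in chosen]
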