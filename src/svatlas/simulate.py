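"""Truth-labelled synthetic inputs for the whole pipeline.

The generator emulates the study design the analysis assumes: a farmed
group plus three wild groups diverged under the Balding–Nichols model
(per-population allele frequency ~ Beta(p(1-F)/F, (1-p)(1-F)/F) around an
ancestral frequency p, giving expected differentiation F), HWE genotypes
within populations, type-specific log-normal SV lengths (medians ~120 bp
deletions, ~619 bp duplications, ~2.5 kb inversions), and
genotype-conditional DHFFC values. A configurable share of records is
planted to violate each filter predicate (gap overlap, high-depth
region, depth-inconsistent carriers, low call rate, low allele count,
translocations, unplaced scaffolds), and a set of "domestication" SVs
receives a planted farmed-vs-wild allele-frequency shift.

Every emitted record carries exactly one truth row. Expected filter
outcomes in the truth table are evaluated directly from the emitted
values (planting determines where violations are likely; the labels are
what the emitted data actually contain), so they are exact oracles for
the deterministic cascade.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import DepthTrack, write_bed, write_sv_vcf
from .model import (
    BedFeature,
    GeneModel,
    Genotype,
    GenomicInterval,
    PopulationPanel,
    SVRecord,
    Transcript,
)

__all__ = [
    "SimConfig",
    "Reference",
    "Cohort",
    "simulate_reference",
    "simulate_cohort",
    "simulate_frequency_cohort",
    "draw_balding_nichols_afs",
    "draw_hwe_genotypes",
    "write_reference",
    "write_cohort",
    "write_gff3",
]


def _default_chroms() -> dict:
    return {f"chr{i}": 2_500_000 for i in range(1, 5)}


def _default_pops() -> dict:
    return {"FARMED": 90, "WILD_A": 13, "WILD_E": 22, "WILD_W": 37}


def _default_lengths() -> dict:
    # (median bp, log-scale sigma); medians follow the empirical
    # per-type medians of short-read SV atlases in farmed fish
    return {"DEL": (120.0, 1.0), "DUP": (619.0, 0.6), "INV": (2456.0, 1.2)}


def _default_dhffc() -> dict:
    # (mean, sd) of the clean genotype-conditional DHFFC distributions
    return {
        ("DEL", "HOM_REF"): (1.0, 0.05),
        ("DEL", "HET"): (0.5, 0.1),
        ("DEL", "HOM_ALT"): (0.05, 0.05),
        ("DUP", "HOM_REF"): (1.0, 0.05),
        ("DUP", "CARRIER"): (1.6, 0.15),
        ("INV", "HOM_REF"): (1.0, 0.05),
        ("INV", "CARRIER"): (1.0, 0.1),
    }


@dataclass
class SimConfig:
    seed: int = 0
    chrom_lengths: dict = field(default_factory=_default_chroms)
    unplaced_name: str = "scaffold_un"
    unplaced_length: int = 200_000
    # gene models
    n_genes: int = 200
    exon_count_range: tuple = (2, 30)
    exon_length_range: tuple = (90, 300)
    intron_length_range: tuple = (100, 800)
    intergene_gap_range: tuple = (2_000, 20_000)
    # reference features
    n_repeats: int = 300
    repeat_length_range: tuple = (60, 600)
    n_gerp: int = 400
    gerp_exonic_fraction: float = 0.6
    n_gaps: int = 8
    gap_length_range: tuple = (2_000, 10_000)
    # depth track
    depth_bin: int = 500
    base_depth: float = 20.0
    depth_sd: float = 2.0
    high_depth_value: float = 150.0
    n_high_depth_segments: int = 5
    high_depth_length_range: tuple = (2_000, 8_000)
    # cohort
    populations: dict = field(default_factory=_default_pops)
    farmed_group: str = "FARMED"
    n_hybrids: int = 8
    fst: float = 0.1  # Balding-Nichols divergence per population
    ancestral_af_range: tuple = (0.05, 0.95)
    # SV numbers (proportions mirror a deletion-dominated short-read call set)
    n_del: int = 1700
    n_dup: int = 200
    n_inv: int = 100
    length_params: dict = field(default_factory=_default_lengths)
    min_sv_length: int = 50
    # planted structure
    n_domestication: int = 50
    domestication_delta_af: float = 0.5
    n_planted_intronic: int = 30
    n_planted_exon_loss: int = 30
    n_planted_fusion: int = 15
    frac_gap_overlap: float = 0.02
    frac_high_depth: float = 0.02
    frac_dhffc_artifact: float = 0.03
    frac_low_callrate: float = 0.02
    frac_low_ac: float = 0.01
    frac_bnd: float = 0.01
    frac_unplaced: float = 0.0075
    low_callrate_missing_frac: float = 0.35
    dhffc_params: dict = field(default_factory=_default_dhffc)

    def __post_init__(self) -> None:
        if not (0 < self.fst < 1):
            raise ValueError("fst must lie in (0, 1)")
        lo, hi = self.ancestral_af_range
        if not (0 <= lo < hi <= 1):
            raise ValueError("bad ancestral AF range")

    @property
    def n_sv(self) -> int:
        return self.n_del + self.n_dup + self.n_inv

    @property
    def whitelist(self) -> frozenset:
        return frozenset(self.chrom_lengths)


@dataclass
class Reference:
    chrom_lengths: dict  # includes the unplaced scaffold
    whitelist: frozenset
    genes: list
    repeats: list
    gerp: list
    gaps: list
    depth: DepthTrack
    high_depth_segments: list  # planted >threshold segments


@dataclass
class Cohort:
    records: list
    roster: list
    panel: PopulationPanel
    truth: pd.DataFrame


# ---------------------------------------------------------------- allele draws

def draw_balding_nichols_afs(p_anc: np.ndarray, F: float,
                             rng: np.random.Generator) -> np.ndarray:
    """Per-population allele frequencies around ancestral p under the
    Balding–Nichols model: Beta(p(1-F)/F, (1-p)(1-F)/F)."""
    p_anc = np.asarray(p_anc, dtype=float)
    scale = (1 - F) / F
    return rng.beta(p_anc * scale, (1 - p_anc) * scale)


def _feasible_shift_signs(anchor: np.ndarray, delta: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Shift directions that keep anchor +/- delta inside [0.02, 0.98],
    so the planted allele-frequency displacement is fully realized;
    random where both directions fit."""
    up_ok = anchor + delta <= 0.98
    dn_ok = anchor - delta >= 0.02
    signs = rng.choice([-1, 1], size=anchor.size)
    signs = np.where(up_ok & ~dn_ok, 1, signs)
    signs = np.where(dn_ok & ~up_ok, -1, signs)
    return signs


def draw_hwe_genotypes(afs: np.ndarray, n_samples: int,
                       rng: np.random.Generator) -> np.ndarray:
    """(n_sv, n_samples) genotype codes drawn as Binomial(2, af) — HWE
    within the population."""
    afs = np.asarray(afs, dtype=float)
    return rng.binomial(2, afs[:, None], size=(afs.size, n_samples)).astype(np.int8)


# ------------------------------------------------------------- reference build

def _make_gene(gene_id: str, chrom: str, pos: int, strand: str,
               rng: np.random.Generator, cfg: SimConfig) -> GeneModel:
    n_exons = int(rng.integers(cfg.exon_count_range[0], cfg.exon_count_range[1] + 1))
    exon_lens = rng.integers(cfg.exon_length_range[0],
                             cfg.exon_length_range[1] + 1, n_exons)
    intron_lens = rng.integers(cfg.intron_length_range[0],
                               cfg.intron_length_range[1] + 1,
                               max(0, n_exons - 1))
    exons = []
    cur = pos
    for i, el in enumerate(exon_lens):
        exons.append((cur, cur + int(el)))
        cur += int(el)
        if i < n_exons - 1:
            cur += int(intron_lens[i])
    start, end = exons[0][0], exons[-1][1]
    # coding region: middle of the first exon to middle of the last exon
    first, last = exons[0], exons[-1]
    cds_lo = (first[0] + first[1]) // 2
    cds_hi = (last[0] + last[1]) // 2
    cds = []
    left_utr = (first[0], cds_lo)
    right_utr = (cds_hi, last[1])
    for s, e in exons:
        cs, ce = max(s, cds_lo), min(e, cds_hi)
        if ce > cs:
            cds.append((cs, ce))
    utr5, utr3 = ([left_utr], [right_utr]) if strand == "+" else ([right_utr], [left_utr])
    tx = Transcript(transcript_id=f"{gene_id}.t1", exons=exons, cds=cds,
                    utr5=utr5, utr3=utr3)
    return GeneModel(gene_id=gene_id, chrom=chrom, start=start, end=end,
                     strand=strand, transcripts=[tx])


def _place_avoiding(length: int, chrom_len: int, avoid: list,
                    rng: np.random.Generator, tries: int = 200) -> Optional[int]:
    for _ in range(tries):
        start = int(rng.integers(0, chrom_len - length))
        if all(start >= e or start + length <= s for s, e in avoid):
            return start
    return None


def simulate_reference(config: SimConfig,
                       rng: Optional[np.random.Generator] = None) -> Reference:
    """Genome layout: non-overlapping gene models, repeats, constrained
    (GERP-like) elements placed preferentially in exons, assembly gaps
    (kept clear of genes), and a binned depth track with planted
    high-depth segments."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    chroms = list(config.chrom_lengths)

    genes: list = []
    per_chrom = {c: [] for c in chroms}
    gi = 0
    chrom_cycle = 0
    cursors = {c: int(rng.integers(2_000, 10_000)) for c in chroms}
    while gi < config.n_genes:
        chrom = chroms[chrom_cycle % len(chroms)]
        chrom_cycle += 1
        strand = "+" if rng.random() < 0.5 else "-"
        gene = _make_gene(f"gene{gi:04d}", chrom, cursors[chrom], strand, rng, config)
        if gene.end > config.chrom_lengths[chrom] - 5_000:
            if all(cursors[c] > config.chrom_lengths[c] - 40_000 for c in chroms):
                raise ValueError("infeasible gene packing: genome too small")
            continue
        gene.validate()
        genes.append(gene)
        per_chrom[chrom].append((gene.start, gene.end))
        cursors[chrom] = gene.end + int(
            rng.integers(config.intergene_gap_range[0],
                         config.intergene_gap_range[1] + 1))
        gi += 1

    # assembly gaps, kept clear of gene bodies
    gaps: list = []
    gap_spans = {c: list(per_chrom[c]) for c in chroms}
    for _ in range(config.n_gaps):
        chrom = chroms[int(rng.integers(len(chroms)))]
        length = int(rng.integers(*config.gap_length_range))
        start = _place_avoiding(length, config.chrom_lengths[chrom],
                                gap_spans[chrom], rng)
        if start is None:
            continue
        gaps.append(GenomicInterval(chrom, start, start + length))
        gap_spans[chrom].append((start, start + length))

    repeats: list = []
    classes = np.array(["Simple_repeat", "LINE", "SINE"])
    class_p = np.array([0.78, 0.13, 0.09])
    for i in range(config.n_repeats):
        chrom = chroms[int(rng.integers(len(chroms)))]
        length = int(rng.integers(*config.repeat_length_range))
        start = int(rng.integers(0, config.chrom_lengths[chrom] - length))
        cls = str(rng.choice(classes, p=class_p))
        repeats.append(BedFeature(chrom, start, start + length, cls))

    gerp: list = []
    all_exons = [(g.chrom, s, e) for g in genes
                 for tx in g.transcripts for s, e in tx.exons]
    n_exonic = int(round(config.n_gerp * config.gerp_exonic_fraction))
    for i in range(config.n_gerp):
        length = int(np.clip(rng.lognormal(np.log(40), 0.8), 10, 500))
        if i < n_exonic and all_exons:
            chrom, es, ee = all_exons[int(rng.integers(len(all_exons)))]
            if ee - es <= length:
                start, end = es, ee
            else:
                start = es + int(rng.integers(0, ee - es - length))
                end = start + length
        else:
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = int(rng.integers(0, config.chrom_lengths[chrom] - length))
            end = start + length
        gerp.append(BedFeature(chrom, start, end, f"gerp{i:05d}"))

    # depth track: binned baseline noise plus planted high-depth segments
    hd_segments: list = []
    frames = []
    hd_spans = {c: list(per_chrom[c]) for c in chroms}
    for _ in range(config.n_high_depth_segments):
        chrom = chroms[int(rng.integers(len(chroms)))]
        length = int(rng.integers(*config.high_depth_length_range))
        length = (length // config.depth_bin) * config.depth_bin or config.depth_bin
        start = _place_avoiding(length, config.chrom_lengths[chrom],
                                hd_spans[chrom], rng)
        if start is None:
            continue
        start = (start // config.depth_bin) * config.depth_bin
        hd_segments.append(GenomicInterval(chrom, start, start + length))
        hd_spans[chrom].append((start, start + length))
    all_chroms = dict(config.chrom_lengths)
    all_chroms[config.unplaced_name] = config.unplaced_length
    for chrom, clen in all_chroms.items():
        edges = np.arange(0, clen + config.depth_bin, config.depth_bin)
        edges[-1] = min(edges[-1], clen)
        starts = edges[:-1]
        ends = edges[1:]
        keep = ends > starts
        starts, ends = starts[keep], ends[keep]
        depth = np.round(np.clip(
            rng.normal(config.base_depth, config.depth_sd, starts.size), 1.0, None), 2)
        for seg in hd_segments:
            if seg.chrom == chrom:
                sel = (starts >= seg.start) & (ends <= seg.end)
                depth[sel] = config.high_depth_value
        frames.append(pd.DataFrame(
            {"chrom": chrom, "start": starts, "end": ends, "depth": depth}))
    depth_track = DepthTrack.from_dataframe(pd.concat(frames, ignore_index=True))

    return Reference(chrom_lengths=all_chroms, whitelist=config.whitelist,
                     genes=genes, repeats=repeats, gerp=gerp, gaps=gaps,
                     depth=depth_track, high_depth_segments=hd_segments)


# --------------------------------------------------------------- cohort build

def _sample_length(svtype: str, cfg: SimConfig, rng: np.random.Generator) -> int:
    median, sigma = cfg.length_params[svtype]
    length = int(rng.lognormal(np.log(median), sigma))
    return max(cfg.min_sv_length, min(length, 100_000))


def _roster(cfg: SimConfig) -> tuple:
    roster, assignment = [], {}
    for pop, size in cfg.populations.items():
        for i in range(size):
            name = f"{pop}_{i + 1:03d}"
            roster.append(name)
            assignment[name] = pop
    hybrids = [f"HYB_{i + 1:03d}" for i in range(cfg.n_hybrids)]
    roster.extend(hybrids)
    panel = PopulationPanel(assignment=assignment, excluded=frozenset(hybrids))
    return roster, panel


@dataclass
class _Slot:
    svtype: str
    role: str  # neutral / domestication / intronic / exon_loss / fusion / fail modes
    chrom: str = ""
    start: int = 0
    end: int = 0
    expected_term: str = ""


def _plan_slots(cfg: SimConfig, ref: Reference, rng: np.random.Generator) -> list:
    n_fail = {
        "gap_overlap": int(round(cfg.frac_gap_overlap * cfg.n_sv)),
        "high_depth": int(round(cfg.frac_high_depth * cfg.n_sv)),
        "dhffc_artifact": int(round(cfg.frac_dhffc_artifact * cfg.n_sv)),
        "low_callrate": int(round(cfg.frac_low_callrate * cfg.n_sv)),
        "low_ac": int(round(cfg.frac_low_ac * cfg.n_sv)),
        "bnd": int(round(cfg.frac_bnd * cfg.n_sv)),
        "unplaced": int(round(cfg.frac_unplaced * cfg.n_sv)),
    }
    slots: list = []
    slots += [_Slot("DEL", "intronic") for _ in range(cfg.n_planted_intronic)]
    slots += [_Slot("DEL", "exon_loss") for _ in range(cfg.n_planted_exon_loss)]
    slots += [_Slot("INV", "fusion") for _ in range(cfg.n_planted_fusion)]
    slots += [_Slot("DEL", "domestication") for _ in range(cfg.n_domestication)]
    for role, n in n_fail.items():
        if role == "bnd":
            slots += [_Slot("BND", role) for _ in range(n)]
        elif role == "dhffc_artifact":
            # spread artifacts across the three types like the real mix
            types = ["DEL"] * (n - n // 4 - n // 8) + ["DUP"] * (n // 4) + ["INV"] * (n // 8)
            slots += [_Slot(t, role) for t in types]
        else:
            slots += [_Slot("DEL", role) for _ in range(n)]
    used = {"DEL": sum(1 for s in slots if s.svtype == "DEL"),
            "DUP": sum(1 for s in slots if s.svtype == "DUP"),
            "INV": sum(1 for s in slots if s.svtype == "INV")}
    budget = {"DEL": cfg.n_del, "DUP": cfg.n_dup, "INV": cfg.n_inv}
    for t in ("DEL", "DUP", "INV"):
        n_neutral = budget[t] - used[t]
        if n_neutral < 0:
            raise ValueError(f"planted {t} records exceed configured count")
        slots += [_Slot(t, "neutral") for _ in range(n_neutral)]
    return slots


def _place_slots(slots: list, cfg: SimConfig, ref: Reference,
                 rng: np.random.Generator) -> None:
    chroms = list(cfg.chrom_lengths)
    gaps_by = {}
    for g in ref.gaps:
        gaps_by.setdefault(g.chrom, []).append((g.start, g.end))
    hd_by = {}
    for seg in ref.high_depth_segments:
        hd_by.setdefault(seg.chrom, []).append((seg.start, seg.end))
    avoid_by = {c: gaps_by.get(c, []) + hd_by.get(c, []) for c in chroms}

    genes_with_intron = [
        g for g in ref.genes
        if any(s2 - e1 >= 80 for tx in g.transcripts
               for (s1, e1), (s2, e2) in zip(tx.exons, tx.exons[1:]))
    ]
    genes_multi_exon = [g for g in ref.genes if len(g.transcripts[0].exons) >= 3]
    genes_sorted = sorted(ref.genes, key=lambda g: (g.chrom, g.start))
    adjacent_pairs = [
        (a, b) for a, b in zip(genes_sorted, genes_sorted[1:])
        if a.chrom == b.chrom and b.start - a.end < 30_000
    ]

    for slot in slots:
        if slot.role == "unplaced":
            length = _sample_length(slot.svtype, cfg, rng)
            length = min(length, cfg.unplaced_length // 4)
            slot.chrom = cfg.unplaced_name
            slot.start = int(rng.integers(0, cfg.unplaced_length - length))
            slot.end = slot.start + length
        elif slot.svtype == "BND":
            slot.chrom = chroms[int(rng.integers(len(chroms)))]
            slot.start = int(rng.integers(0, cfg.chrom_lengths[slot.chrom] - 1))
            slot.end = slot.start + 1
        elif slot.role == "intronic":
            g = genes_with_intron[int(rng.integers(len(genes_with_intron)))]
            tx = g.transcripts[0]
            introns = [(e1, s2) for (s1, e1), (s2, e2) in zip(tx.exons, tx.exons[1:])
                       if s2 - e1 >= 80]
            ilo, ihi = introns[int(rng.integers(len(introns)))]
            margin = 5
            max_len = ihi - ilo - 2 * margin
            length = min(_sample_length("DEL", cfg, rng), max_len)
            length = max(length, min(cfg.min_sv_length, max_len))
            slot.chrom = g.chrom
            slot.start = ilo + margin + int(rng.integers(0, max_len - length + 1))
            slot.end = slot.start + length
            slot.expected_term = "intron_variant"
        elif slot.role == "exon_loss":
            g = genes_multi_exon[int(rng.integers(len(genes_multi_exon)))]
            tx = g.transcripts[0]
            n_exons = len(tx.exons)
            i = int(rng.integers(1, n_exons - 1))  # internal exon
            prev_end = tx.exons[i - 1][1]
            next_start = tx.exons[i + 1][0]
            slot.chrom = g.chrom
            slot.start = prev_end + max(1, (tx.exons[i][0] - prev_end) // 2)
            slot.end = tx.exons[i][1] + max(1, (next_start - tx.exons[i][1]) // 2)
            slot.expected_term = "exon_loss_variant"
        elif slot.role == "fusion":
            ga, gb = adjacent_pairs[int(rng.integers(len(adjacent_pairs)))]
            tx_a, tx_b = ga.transcripts[0], gb.transcripts[0]
            # breakpoints inside the first intron of each gene body
            b1 = (tx_a.exons[0][1] + tx_a.exons[1][0]) // 2 \
                if len(tx_a.exons) > 1 else ga.start + 1
            b2 = (tx_b.exons[-2][1] + tx_b.exons[-1][0]) // 2 \
                if len(tx_b.exons) > 1 else gb.end - 2
            slot.chrom = ga.chrom
            slot.start, slot.end = b1, b2 + 1
            slot.expected_term = ("gene_fusion" if ga.strand == gb.strand
                                  else "bidirectional_gene_fusion")
        elif slot.role == "gap_overlap":
            gap = ref.gaps[int(rng.integers(len(ref.gaps)))]
            length = max(_sample_length(slot.svtype, cfg, rng), 100)
            slot.chrom = gap.chrom
            # start inside the gap so >= 1 bp overlap is guaranteed
            slot.start = int(rng.integers(gap.start, gap.end - 1))
            slot.end = slot.start + length
        elif slot.role == "high_depth":
            seg = ref.high_depth_segments[int(rng.integers(len(ref.high_depth_segments)))]
            length = max(_sample_length(slot.svtype, cfg, rng), 100)
            slot.chrom = seg.chrom
            slot.start = int(rng.integers(seg.start, seg.end - 1))
            slot.end = slot.start + length
        else:  # neutral-like placement, clear of gaps and planted high depth
            length = _sample_length(slot.svtype, cfg, rng)
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = _place_avoiding(length, cfg.chrom_lengths[chrom],
                                    avoid_by[chrom], rng)
            if start is None:
                chrom = chroms[0]
                start = _place_avoiding(length, cfg.chrom_lengths[chrom],
                                        avoid_by[chrom], rng)
                if start is None:
                    raise ValueError("could not place SV clear of gaps")
            slot.chrom = chrom
            slot.start = start
            slot.end = start + length


def _overlaps_spans(chrom: str, start: int, end: int, spans_by: dict) -> bool:
    return any(start < e and s < end for s, e in spans_by.get(chrom, ()))


def simulate_cohort(config: SimConfig, reference: Reference,
                    rng: Optional[np.random.Generator] = None) -> Cohort:
    """Generate the genotyped cohort over the reference, with truth."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    cfg = config
    roster, panel = _roster(cfg)
    n_samples = len(roster)
    pops = list(cfg.populations)
    pop_idx = {p: panel.indices_in(roster, p) for p in pops}
    hybrid_idx = np.array([i for i, s in enumerate(roster)
                           if s in panel.excluded], dtype=int)

    slots = _plan_slots(cfg, reference, rng)
    _place_slots(slots, cfg, reference, rng)
    n_sv = len(slots)

    # allele frequencies
    p_anc = rng.uniform(*cfg.ancestral_af_range, size=n_sv)
    pop_afs = {p: draw_balding_nichols_afs(p_anc, cfg.fst, rng) for p in pops}
    dom_rows = [i for i, s in enumerate(slots) if s.role == "domestication"]
    dom_direction = np.zeros(n_sv, dtype=int)
    if dom_rows:
        # planted contrast is against a common wild baseline: the wild
        # groups share one AF (the ancestral draw) and the farmed group
        # is displaced from it by exactly delta_af
        wild_pops = [p for p in pops if p != cfg.farmed_group]
        wild_af = p_anc[dom_rows]
        for p in wild_pops:
            pop_afs[p][dom_rows] = wild_af
        signs = _feasible_shift_signs(wild_af, cfg.domestication_delta_af, rng)
        shifted = np.clip(wild_af + signs * cfg.domestication_delta_af, 0.02, 0.98)
        pop_afs[cfg.farmed_group][dom_rows] = shifted
        dom_direction[dom_rows] = signs
    lowac_rows = [i for i, s in enumerate(slots) if s.role == "low_ac"]
    for p in pops:
        pop_afs[p][lowac_rows] = 0.004  # expected cohort AC ~ 1

    # genotypes under HWE within populations; hybrids drawn at ancestral AF
    G = np.zeros((n_sv, n_samples), dtype=np.int8)
    for p in pops:
        G[:, pop_idx[p]] = draw_hwe_genotypes(pop_afs[p], pop_idx[p].size, rng)
    if hybrid_idx.size:
        G[:, hybrid_idx] = draw_hwe_genotypes(p_anc, hybrid_idx.size, rng)
    for i in [j for j, s in enumerate(slots) if s.role == "low_callrate"]:
        n_miss = int(round(cfg.low_callrate_missing_frac * n_samples))
        miss = rng.choice(n_samples, size=n_miss, replace=False)
        G[i, miss] = Genotype.MISSING

    # DHFFC, genotype-conditional
    D = np.full((n_sv, n_samples), np.nan)
    for i, slot in enumerate(slots):
        if slot.svtype == "BND":
            continue
        g = G[i]
        d = np.empty(n_samples)
        href = g == Genotype.HOM_REF
        carrier = (g == Genotype.HET) | (g == Genotype.HOM_ALT)
        mu, sd = cfg.dhffc_params[(slot.svtype, "HOM_REF")]
        d[href] = rng.normal(mu, sd, int(href.sum()))
        if slot.role == "dhffc_artifact":
            # carriers emitted strictly inside the masking region
            if slot.svtype == "DEL":
                d[carrier] = rng.uniform(0.75, 1.2, int(carrier.sum()))
            elif slot.svtype == "DUP":
                d[carrier] = rng.uniform(0.75, 1.25, int(carrier.sum()))
            else:
                d[carrier] = rng.uniform(0.75, 1.25, int(carrier.sum()))
        elif slot.svtype == "DEL":
            het = g == Genotype.HET
            halt = g == Genotype.HOM_ALT
            mu, sd = cfg.dhffc_params[("DEL", "HET")]
            d[het] = rng.normal(mu, sd, int(het.sum()))
            mu, sd = cfg.dhffc_params[("DEL", "HOM_ALT")]
            d[halt] = rng.normal(mu, sd, int(halt.sum()))
        else:
            mu, sd = cfg.dhffc_params[(slot.svtype, "CARRIER")]
            d[carrier] = rng.normal(mu, sd, int(carrier.sum()))
        d[g == Genotype.MISSING] = np.nan
        D[i] = np.clip(d, 0.0, None)

    records: list = []
    for i, slot in enumerate(slots):
        records.append(SVRecord(
            id=f"sv{i:05d}", chrom=slot.chrom, start=slot.start, end=slot.end,
            svtype=slot.svtype, genotypes=G[i],
            dhffc=None if slot.svtype == "BND" else D[i]))

    truth = _build_truth(slots, records, cfg, reference, pops, pop_afs,
                         p_anc, dom_direction, panel, roster)
    return Cohort(records=records, roster=roster, panel=panel, truth=truth)


def _build_truth(slots, records, cfg: SimConfig, ref: Reference, pops,
                 pop_afs, p_anc, dom_direction, panel, roster) -> pd.DataFrame:
    """Expected filter outcomes evaluated directly from the emitted
    data — the deterministic oracle for the cascade."""
    gaps_by: dict = {}
    for g in ref.gaps:
        gaps_by.setdefault(g.chrom, []).append((g.start, g.end))
    # high-depth regions recomputed by thresholding the emitted track
    hd_by: dict = {}
    for chrom, (starts, ends, depths) in ref.depth.segments.items():
        cur = None
        for s, e, dv in zip(starts, ends, depths):
            if dv > 100.0:
                if cur is not None and s <= cur[1]:
                    cur = (cur[0], e)
                else:
                    if cur is not None:
                        hd_by.setdefault(chrom, []).append(cur)
                    cur = (s, e)
            else:
                if cur is not None:
                    hd_by.setdefault(chrom, []).append(cur)
                    cur = None
        if cur is not None:
            hd_by.setdefault(chrom, []).append(cur)

    lo_band, hi_band = 0.7, 1.3
    rows = []
    for i, (slot, rec) in enumerate(zip(slots, records)):
        fails_chrom = rec.chrom not in cfg.whitelist
        is_bnd = rec.svtype == "BND"
        fails_gap = _overlaps_spans(rec.chrom, rec.start, rec.end, gaps_by)
        fails_hd = _overlaps_spans(rec.chrom, rec.start, rec.end, hd_by)
        site_removed = fails_chrom or is_bnd or fails_gap or fails_hd

        masked_idx: list = []
        if not is_bnd and rec.dhffc is not None:
            for j in range(rec.n_samples):
                g = int(rec.genotypes[j])
                d = rec.dhffc[j]
                if g not in (Genotype.HET, Genotype.HOM_ALT) or not np.isfinite(d):
                    continue
                if rec.svtype == "DEL" and d > 0.7:
                    masked_idx.append(j)
                elif rec.svtype == "DUP" and d < 1.3:
                    masked_idx.append(j)
                elif rec.svtype == "INV" and lo_band < d < hi_band:
                    masked_idx.append(j)
        g_post = rec.genotypes.copy()
        if masked_idx:
            g_post[np.array(masked_idx, dtype=int)] = Genotype.MISSING
        ac = int(np.sum(g_post == Genotype.HET) + 2 * np.sum(g_post == Genotype.HOM_ALT))
        cr = float(np.mean(g_post != Genotype.MISSING))
        fails_ac = ac <= 2
        fails_cr = cr < 0.80

        if fails_chrom:
            reason = "chromosome"
        elif is_bnd:
            reason = "translocation"
        elif fails_gap:
            reason = "gap_overlap"
        elif fails_hd:
            reason = "high_depth"
        elif fails_ac:
            reason = "low_allele_count"
        elif fails_cr:
            reason = "low_call_rate"
        else:
            reason = ""

        row = {
            "sv_id": rec.id, "chrom": rec.chrom, "start": rec.start,
            "end": rec.end, "svtype": rec.svtype,
            "length": rec.end - rec.start if not is_bnd else np.nan,
            "role": slot.role,
            "ancestral_af": p_anc[i],
            "is_domestication": slot.role == "domestication",
            "dom_direction": int(dom_direction[i]),
            "planted_consequence": slot.role if slot.expected_term else "",
            "expected_term": slot.expected_term,
            "fails_chrom": fails_chrom,
            "is_bnd": is_bnd,
            "fails_gap": fails_gap,
            "fails_high_depth": fails_hd,
            "n_masked": len(masked_idx),
            "masked_samples": ";".join(roster[j] for j in masked_idx),
            "fails_ac_postmask": bool(fails_ac and not site_removed),
            "fails_callrate_postmask": bool(fails_cr and not site_removed),
            "expected_removed": bool(reason),
            "expected_reason": reason,
        }
        for p in pops:
            row[f"af_{p}"] = pop_afs[p][i]
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_frequency_cohort(n_neutral: int, populations: dict, fst: float,
                              rng: np.random.Generator,
                              farmed_group: Optional[str] = None,
                              n_planted: int = 0, delta_af: float = 0.5,
                              ancestral_af_range: tuple = (0.05, 0.95)) -> tuple:
    """Lightweight cohort for allele-frequency analyses: Balding–Nichols
    AFs, HWE genotypes, optional planted farmed-vs-wild shifts. Skips the
    genomic placement and depth machinery; records get synthetic
    coordinates on one chromosome.

    Returns (records, roster, panel, truth DataFrame).
    """
    pops = list(populations)
    if farmed_group is None:
        farmed_group = pops[0]
    n_sv = n_neutral + n_planted
    p_anc = rng.uniform(*ancestral_af_range, size=n_sv)
    pop_afs = {p: draw_balding_nichols_afs(p_anc, fst, rng) for p in pops}
    planted = np.zeros(n_sv, dtype=bool)
    direction = np.zeros(n_sv, dtype=int)
    if n_planted:
        rows = np.arange(n_neutral, n_sv)
        planted[rows] = True
        wild = [p for p in pops if p != farmed_group]
        wild_af = p_anc[rows]
        for p in wild:
            pop_afs[p][rows] = wild_af
        signs = _feasible_shift_signs(wild_af, delta_af, rng)
        pop_afs[farmed_group][rows] = np.clip(
            wild_af + signs * delta_af, 0.02, 0.98)
        direction[rows] = signs

    roster, assignment = [], {}
    for p in pops:
        for i in range(populations[p]):
            s = f"{p}_{i + 1:03d}"
            roster.append(s)
            assignment[s] = p
    panel = PopulationPanel(assignment=assignment)
    G = np.zeros((n_sv, len(roster)), dtype=np.int8)
    for p in pops:
        idx = panel.indices_in(roster, p)
        G[:, idx] = draw_hwe_genotypes(pop_afs[p], idx.size, rng)
    records = [
        SVRecord(id=f"sv{i:06d}", chrom="chr1", start=i * 1000,
                 end=i * 1000 + 100, svtype="DEL", genotypes=G[i])
        for i in range(n_sv)
    ]
    truth = pd.DataFrame({
        "sv_id": [r.id for r in records],
        "ancestral_af": p_anc,
        "planted": planted,
        "direction": direction,
        **{f"af_{p}": pop_afs[p] for p in pops},
    })
    return records, roster, panel, truth


# ---------------------------------------------------------------- file output

def write_gff3(genes: Sequence[GeneModel], path: str) -> None:
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            out.write(f"{g.chrom}\tsim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n")
            for tx in g.transcripts:
                out.write(f"{g.chrom}\tsim\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                          f"ID={tx.transcript_id};Parent={g.gene_id}\n")
                for kind, ivls in (("exon", tx.exons), ("CDS", tx.cds),
                                   ("five_prime_UTR", tx.utr5),
                                   ("three_prime_UTR", tx.utr3)):
                    for s, e in ivls:
                        out.write(f"{g.chrom}\tsim\t{kind}\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                                  f"Parent={tx.transcript_id}\n")


def write_reference(ref: Reference, outdir: str) -> dict:
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "genome": os.path.join(outdir, "genome.tsv"),
        "genes": os.path.join(outdir, "genes.gff3"),
        "repeats": os.path.join(outdir, "repeats.bed"),
        "gerp": os.path.join(outdir, "gerp.bed"),
        "gaps": os.path.join(outdir, "gaps.bed"),
        "depth": os.path.join(outdir, "depth.bedgraph"),
    }
    with open(paths["genome"], "w") as out:
        for chrom, length in ref.chrom_lengths.items():
            wl = 1 if chrom in ref.whitelist else 0
            out.write(f"{chrom}\t{length}\t{wl}\n")
    write_gff3(ref.genes, paths["genes"])
    write_bed(ref.repeats, paths["repeats"])
    write_bed(ref.gerp, paths["gerp"])
    write_bed([BedFeature(g.chrom, g.start, g.end, "gap") for g in ref.gaps],
              paths["gaps"])
    ref.depth.write(paths["depth"])
    return paths


def write_cohort(cohort: Cohort, ref: Reference, outdir: str) -> dict:
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "vcf": os.path.join(outdir, "cohort.vcf"),
        "pops": os.path.join(outdir, "pops.tsv"),
        "truth": os.path.join(outdir, "truth_svs.tsv"),
    }
    write_sv_vcf(cohort.records, cohort.roster, paths["vcf"],
                 contig_lengths=ref.chrom_lengths)
    with open(paths["pops"], "w") as out:
        for s in cohort.roster:
            if s in cohort.panel.excluded:
                out.write(f"{s}\t-\thybrid\n")
            else:
                out.write(f"{s}\t{cohort.panel.assignment[s]}\n")
    cohort.truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.6g")
    return paths
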