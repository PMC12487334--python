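"""The five-step post-calling filter cascade for genotyped SVs.

Order is fixed: site-level filters (chromosome whitelist, translocation
removal, gap / high-depth overlap) -> depth-consistency genotype masking
(DHFFC) -> allele-count and call-rate filters. The AC/call-rate step must
see masked genotypes, so the order is part of the contract.

DHFFC is Duphold's fold-change of mean depth inside the SV relative to
its flanking regions: a true heterozygous deletion sits near 0.5, a true
duplication carrier above ~1.3, while an artifact call shows no depth
change (DHFFC ~ 1). Masking applies to carrier genotypes only — for a
non-carrier a fold-change of ~1 is the expected signal, not evidence
against the call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io import DepthTrack
from .model import GenomicInterval, Genotype, SVRecord

__all__ = [
    "FilterConfig",
    "FilterReport",
    "compute_high_depth_regions",
    "compute_dhffc",
    "filter_sites",
    "mask_genotypes_dhffc",
    "filter_ac_callrate",
    "run_filter_cascade",
]


@dataclass
class FilterConfig:
    """Thresholds of the cascade (defaults follow the published pipeline).

    dhffc_del_max: carriers of a deletion are masked when DHFFC > this.
    dhffc_dup_min: carriers of a duplication are masked when DHFFC < this.
    dhffc_inv_band: inversion carriers are masked strictly inside this band.
    min_allele_count: sites with ALT allele count <= this are removed.
    min_call_rate: sites with call rate < this are removed (== survives).
    depth_threshold: regions with mean depth > this are 'high-depth'.
    """

    chrom_whitelist: Optional[frozenset] = None  # None = no whitelist filter
    depth_threshold: float = 100.0
    dhffc_del_max: float = 0.7
    dhffc_dup_min: float = 1.3
    dhffc_inv_band: tuple = (0.7, 1.3)
    min_allele_count: int = 2
    min_call_rate: float = 0.80
    flank_bp: int = 1000

    def __post_init__(self) -> None:
        if not (0 < self.dhffc_del_max < self.dhffc_dup_min):
            raise ValueError("require 0 < dhffc_del_max < dhffc_dup_min")
        if not (0 < self.min_call_rate <= 1):
            raise ValueError("min_call_rate must be in (0, 1]")
        if self.chrom_whitelist is not None:
            self.chrom_whitelist = frozenset(self.chrom_whitelist)


@dataclass
class StepCounts:
    step: str
    n_input: int
    n_removed: int

    @property
    def n_surviving(self) -> int:
        return self.n_input - self.n_removed


@dataclass
class FilterReport:
    steps: list = field(default_factory=list)
    removal_reasons: dict = field(default_factory=dict)  # sv_id -> reason
    n_genotypes_masked: int = 0
    masked_genotypes: dict = field(default_factory=dict)  # sv_id -> sample indices

    def add_step(self, step: str, n_input: int, n_removed: int) -> None:
        self.steps.append(StepCounts(step, n_input, n_removed))

    def validate_telescoping(self) -> None:
        for prev, cur in zip(self.steps, self.steps[1:]):
            if cur.n_input != prev.n_surviving:
                raise AssertionError(
                    f"counts do not telescope between {prev.step} and {cur.step}")


def compute_high_depth_regions(track: DepthTrack, threshold: float = 100.0) -> list:
    """Maximal merged intervals where mean segment depth is strictly
    above ``threshold``. Adjacent/contiguous passing segments merge."""
    regions: list = []
    for chrom, (starts, ends, depths) in track.segments.items():
        passing = depths > threshold
        cur_start = cur_end = None
        for s, e, ok in zip(starts, ends, passing):
            if not ok:
                if cur_start is not None:
                    regions.append(GenomicInterval(chrom, int(cur_start), int(cur_end)))
                    cur_start = None
                continue
            if cur_start is not None and s <= cur_end:
                cur_end = e
            else:
                if cur_start is not None:
                    regions.append(GenomicInterval(chrom, int(cur_start), int(cur_end)))
                cur_start, cur_end = s, e
        if cur_start is not None:
            regions.append(GenomicInterval(chrom, int(cur_start), int(cur_end)))
    return regions


def compute_dhffc(track: DepthTrack, sv: GenomicInterval,
                  flank_bp: int = 1000) -> Optional[float]:
    """(mean depth inside the SV) / (joint mean depth over both flanks).

    Flanks are clipped at the chromosome's track extent; the denominator
    is the length-weighted mean over both flanks jointly. A zero/empty
    flank mean yields None (no depth evidence), not infinity.
    """
    lo, hi = track.chrom_extent(sv.chrom)
    if sv.start < lo or sv.end > hi:
        raise ValueError(f"SV {sv.chrom}:{sv.start}-{sv.end} outside depth track")
    inside = track.mean_depth(sv.chrom, sv.start, sv.end)
    left = (max(lo, sv.start - flank_bp), sv.start)
    right = (sv.end, min(hi, sv.end + flank_bp))
    num = 0.0
    denom_bp = 0
    for fs, fe in (left, right):
        if fe > fs:
            m = track.mean_depth(sv.chrom, fs, fe)
            if np.isfinite(m):
                num += m * (fe - fs)
                denom_bp += fe - fs
    if denom_bp == 0:
        return None
    flank_mean = num / denom_bp
    if flank_mean == 0 or not np.isfinite(inside):
        return None
    return float(inside / flank_mean)


def _overlaps_any(rec: SVRecord, intervals_by_chrom: dict) -> bool:
    for start, end in intervals_by_chrom.get(rec.chrom, ()):
        if rec.start < end and start < rec.end:
            return True
    return False


def _index_intervals(intervals: Sequence[GenomicInterval]) -> dict:
    out: dict = {}
    for ivl in intervals:
        out.setdefault(ivl.chrom, []).append((ivl.start, ivl.end))
    return out


def filter_sites(records: Sequence[SVRecord], config: FilterConfig,
                 gaps: Sequence[GenomicInterval] = (),
                 high_depth: Sequence[GenomicInterval] = ()) -> tuple:
    """Site-level steps: chromosome whitelist, translocation (BND)
    removal, and removal of records overlapping (>= 1 bp) any assembly
    gap or high-depth region. Returns (survivors, report_entries)."""
    gap_idx = _index_intervals(gaps)
    hd_idx = _index_intervals(high_depth)
    survivors: list = []
    reasons: dict = {}
    counts = {"chromosome": 0, "translocation": 0, "gap_overlap": 0, "high_depth": 0}
    for rec in records:
        if config.chrom_whitelist is not None and rec.chrom not in config.chrom_whitelist:
            reasons[rec.id] = "chromosome"
        elif rec.svtype == "BND":
            reasons[rec.id] = "translocation"
        elif _overlaps_any(rec, gap_idx):
            reasons[rec.id] = "gap_overlap"
        elif _overlaps_any(rec, hd_idx):
            reasons[rec.id] = "high_depth"
        else:
            survivors.append(rec)
            continue
        counts[reasons[rec.id]] += 1
    return survivors, reasons, counts


def mask_genotypes_dhffc(records: Sequence[SVRecord],
                         config: FilterConfig) -> tuple:
    """Replace depth-inconsistent carrier genotypes with MISSING.

    DEL carriers: masked when DHFFC > dhffc_del_max (strict).
    DUP carriers: masked when DHFFC < dhffc_dup_min (strict).
    INV carriers: masked when DHFFC strictly inside dhffc_inv_band.
    HOM_REF and MISSING calls are never touched; a carrier without a
    DHFFC value is retained (mask only on positive depth evidence).
    Returns (new records, {sv_id: masked sample index array}).
    """
    lo_band, hi_band = config.dhffc_inv_band
    out: list = []
    masked_by_record: dict = {}
    for rec in records:
        if rec.dhffc is None or rec.svtype == "BND":
            out.append(rec)
            continue
        carrier = (rec.genotypes == Genotype.HET) | (rec.genotypes == Genotype.HOM_ALT)
        d = rec.dhffc
        with np.errstate(invalid="ignore"):
            if rec.svtype == "DEL":
                bad = d > config.dhffc_del_max
            elif rec.svtype == "DUP":
                bad = d < config.dhffc_dup_min
            else:  # INV
                bad = (d > lo_band) & (d < hi_band)
        mask = carrier & bad & np.isfinite(d)
        if mask.any():
            new = rec.copy()
            new.genotypes[mask] = Genotype.MISSING
            out.append(new)
            masked_by_record[rec.id] = np.flatnonzero(mask)
        else:
            out.append(rec)
    return out, masked_by_record


def allele_count(rec: SVRecord) -> int:
    """ALT allele count over non-missing genotypes (HET=1, HOM_ALT=2)."""
    g = rec.genotypes
    return int(np.sum(g == Genotype.HET) + 2 * np.sum(g == Genotype.HOM_ALT))


def call_rate(rec: SVRecord) -> float:
    return float(np.mean(rec.genotypes != Genotype.MISSING))


def filter_ac_callrate(records: Sequence[SVRecord],
                       config: FilterConfig) -> tuple:
    """Remove sites with AC <= min_allele_count or call rate strictly
    below min_call_rate (a rate of exactly the threshold survives)."""
    survivors: list = []
    reasons: dict = {}
    counts = {"low_allele_count": 0, "low_call_rate": 0}
    for rec in records:
        low_ac = allele_count(rec) <= config.min_allele_count
        low_cr = call_rate(rec) < config.min_call_rate
        if low_ac:
            reasons[rec.id] = "low_allele_count"
            counts["low_allele_count"] += 1
        elif low_cr:
            reasons[rec.id] = "low_call_rate"
            counts["low_call_rate"] += 1
        else:
            survivors.append(rec)
    return survivors, reasons, counts


_SITE_STEPS = ("chromosome", "translocation", "gap_overlap", "high_depth")
_AC_STEPS = ("low_allele_count", "low_call_rate")


def run_filter_cascade(records: Sequence[SVRecord], config: FilterConfig,
                       gaps: Sequence[GenomicInterval] = (),
                       high_depth: Sequence[GenomicInterval] = (),
                       depth_track: Optional[DepthTrack] = None) -> tuple:
    """Full cascade; returns (survivors, FilterReport).

    ``high_depth`` intervals may be supplied directly or derived from a
    depth track. When records lack per-sample DHFFC and a depth track is
    given, a record-level DHFFC is computed from the track and applied to
    every carrier.
    """
    if depth_track is not None and not high_depth:
        high_depth = compute_high_depth_regions(depth_track, config.depth_threshold)
    if depth_track is not None:
        filled = []
        for rec in records:
            if rec.dhffc is None and rec.svtype != "BND":
                v = compute_dhffc(depth_track, rec.interval, config.flank_bp)
                new = rec.copy()
                new.dhffc = np.full(rec.n_samples, np.nan if v is None else v)
                filled.append(new)
            else:
                filled.append(rec)
        records = filled

    report = FilterReport()
    records = list(records)
    n0 = len(records)

    survivors, site_reasons, site_counts = filter_sites(
        records, config, gaps=gaps, high_depth=high_depth)
    report.removal_reasons.update(site_reasons)
    n_in = n0
    for step in _SITE_STEPS:
        report.add_step(step, n_in, site_counts[step])
        n_in -= site_counts[step]

    masked, masked_by_record = mask_genotypes_dhffc(survivors, config)
    report.masked_genotypes = masked_by_record
    report.n_genotypes_masked = int(sum(len(v) for v in masked_by_record.values()))
    report.add_step("dhffc_masking", n_in, 0)  # masks genotypes, removes no site

    final, ac_reasons, ac_counts = filter_ac_callrate(masked, config)
    report.removal_reasons.update(ac_reasons)
    for step in _AC_STEPS:
        report.add_step(step, n_in, ac_counts[step])
        n_in -= ac_counts[step]
    report.validate_telescoping()
    return final, report
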