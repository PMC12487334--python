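"""Core domain types shared across the toolkit.

All coordinates are 0-based half-open internally. VCF and GFF3 (both
1-based inclusive) are converted at the I/O boundary; BED passes through
unchanged. Genotypes are stored as small integer codes so that cohort-wide
operations can run on numpy arrays.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "Genotype",
    "GenomicInterval",
    "BedFeature",
    "SVRecord",
    "Transcript",
    "GeneModel",
    "PopulationPanel",
    "SV_TYPES",
]

SV_TYPES = ("DEL", "DUP", "INV", "BND")


class Genotype(enum.IntEnum):
    """Diploid genotype states for a biallelic structural variant."""

    MISSING = -1
    HOM_REF = 0
    HET = 1
    HOM_ALT = 2


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval [start, end) on a chromosome (0-based)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.end <= self.start:
            raise ValueError(
                f"end ({self.end}) must exceed start ({self.start}) on {self.chrom}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Number of shared bases with *other*; 0 if different chromosomes."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.overlap_bp(other) > 0

    def contains(self, other: "GenomicInterval") -> bool:
        """True when *other* lies fully within this interval (same chrom)."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def distance_to(self, other: "GenomicInterval") -> int:
        """Gap in bp between non-overlapping intervals; 0 when touching/overlapping."""
        if self.chrom != other.chrom:
            raise ValueError("distance undefined across chromosomes")
        if self.overlaps(other):
            return 0
        if other.start >= self.end:
            return other.start - self.end
        return self.start - other.end


@dataclass(frozen=True)
class BedFeature:
    """One BED line: an interval plus the optional name/class column."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SVRecord:
    """A genotyped structural variant.

    ``genotypes`` holds one :class:`Genotype` code per sample in roster
    order; ``dhffc`` holds the per-sample depth fold-change (NaN when the
    genotyper emitted no depth evidence), or ``None`` when the dataset
    carries no DHFFC annotation at all.
    """

    id: str
    chrom: str
    start: int
    end: int
    svtype: str
    genotypes: np.ndarray
    dhffc: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.svtype not in SV_TYPES:
            raise ValueError(f"unknown SVTYPE {self.svtype!r} for {self.id}")
        if self.end <= self.start:
            raise ValueError(f"record {self.id}: END must exceed POS")
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.dhffc is not None:
            self.dhffc = np.asarray(self.dhffc, dtype=float)
            if self.dhffc.shape != self.genotypes.shape:
                raise ValueError(f"record {self.id}: DHFFC/genotype shape mismatch")

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)

    @property
    def length(self) -> Optional[int]:
        """Breakpoint span end - start; undefined (None) for BND."""
        if self.svtype == "BND":
            return None
        return self.end - self.start

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    def copy(self) -> "SVRecord":
        return SVRecord(
            id=self.id,
            chrom=self.chrom,
            start=self.start,
            end=self.end,
            svtype=self.svtype,
            genotypes=self.genotypes.copy(),
            dhffc=None if self.dhffc is None else self.dhffc.copy(),
        )


@dataclass
class Transcript:
    transcript_id: str
    exons: list  # sorted disjoint (start, end) tuples
    cds: list = field(default_factory=list)
    utr5: list = field(default_factory=list)
    utr3: list = field(default_factory=list)

    def validate(self, gene_id: str = "?") -> None:
        for name, ivls in (("exons", self.exons), ("cds", self.cds)):
            for s, e in ivls:
                if e <= s:
                    raise ValueError(f"{gene_id}/{self.transcript_id}: empty {name} interval")
        for cs, ce in self.cds:
            if not any(es <= cs and ce <= ee for es, ee in self.exons):
                raise ValueError(
                    f"{gene_id}/{self.transcript_id}: CDS [{cs},{ce}) outside exon union"
                )

    @property
    def span(self) -> tuple:
        lo = min(s for s, _ in self.exons)
        hi = max(e for _, e in self.exons)
        return lo, hi


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    transcripts: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)

    def validate(self) -> None:
        for tx in self.transcripts:
            tx.validate(self.gene_id)
            lo, hi = tx.span
            if lo < self.start or hi > self.end:
                raise ValueError(f"gene {self.gene_id}: exon outside gene interval")


@dataclass
class PopulationPanel:
    """Sample-to-group assignment with an explicit exclusion set.

    Excluded samples (e.g. experimentally produced F1 hybrids) never enter
    any statistic.
    """

    assignment: dict
    excluded: frozenset = frozenset()

    def __post_init__(self) -> None:
        self.excluded = frozenset(self.excluded)
        clash = self.excluded & set(self.assignment)
        if clash:
            raise ValueError(f"samples both assigned and excluded: {sorted(clash)}")

    @property
    def groups(self) -> dict:
        out: dict = {}
        for sample, grp in self.assignment.items():
            out.setdefault(grp, []).append(sample)
        return out

    def samples_in(self, group: str) -> list:
        return [s for s, g in self.assignment.items() if g == group]

    def indices_in(self, roster: list, group: str) -> np.ndarray:
        members = set(self.samples_in(group))
        return np.array([i for i, s in enumerate(roster) if s in members], dtype=int)
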