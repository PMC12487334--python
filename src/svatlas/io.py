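"""Readers and writers for the standard formats the pipeline touches.

Conversions happen only here: VCF POS/END (1-based inclusive) and GFF3
(1-based inclusive) become 0-based half-open; BED and bedGraph pass
through. Readers preserve record and sample order and never silently drop
a well-formed line — rejected lines are counted through the module logger.
"""

from __future__ import annotations

import logging
import os
import tempfile
from dataclasses import dataclass
from typing import Iterable, Optional

import gffutils
import numpy as np
import pandas as pd
import pysam

from .model import (
    BedFeature,
    GeneModel,
    Genotype,
    GenomicInterval,
    PopulationPanel,
    SVRecord,
    SV_TYPES,
    Transcript,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_sv_vcf",
    "write_sv_vcf",
    "read_bed",
    "write_bed",
    "read_gff3",
    "read_population_map",
    "DepthTrack",
    "read_depth_track",
]


def _gt_to_code(gt: tuple) -> int:
    if gt is None or any(a is None for a in gt):
        return int(Genotype.MISSING)
    n_alt = sum(1 for a in gt if a != 0)
    if len(gt) == 1:  # haploid call, treated as hom
        n_alt *= 2
    return min(n_alt, 2)


def _validate_end_coordinates(path: str) -> None:
    """Hard error on END < POS. htslib silently drops such an END (with
    a stderr warning), so this is checked on the raw INFO text before
    parsing."""
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.split("\t", 8)
            if len(fields) < 8:
                continue
            for entry in fields[7].split(";"):
                if entry.startswith("END="):
                    try:
                        end = int(entry[4:])
                    except ValueError:
                        break
                    if end < int(fields[1]):
                        raise ValueError(
                            f"record {fields[2]} at {fields[0]}:{fields[1]}: "
                            f"END ({end}) < POS")
                    break


def read_sv_vcf(path: str) -> tuple:
    """Read a multi-sample SV VCF into :class:`SVRecord` objects.

    Returns ``(records, roster)``. Records without an SVTYPE INFO field are
    rejected with a warning; END < POS is a hard error naming the record.
    BND records (no meaningful END) get the 1-bp interval at their
    breakpoint so they remain addressable until the filter cascade removes
    them.
    """
    _validate_end_coordinates(path)
    records: list = []
    with pysam.VariantFile(path) as vf:
        roster = list(vf.header.samples)
        for i, rec in enumerate(vf):
            svtype = rec.info.get("SVTYPE")
            if svtype is None:
                logger.warning("record %s at %s:%s has no SVTYPE; rejected",
                               rec.id, rec.chrom, rec.pos)
                continue
            if svtype not in SV_TYPES:
                logger.warning("record %s: unsupported SVTYPE %s; rejected", rec.id, svtype)
                continue
            start = rec.pos - 1  # pysam .pos is 1-based
            if svtype == "BND":
                end = start + 1
            else:
                end = rec.stop  # pysam .stop is already 0-based exclusive (== END)
                if end <= start:
                    raise ValueError(
                        f"record {rec.id or i} at {rec.chrom}:{rec.pos}: END < POS"
                    )
            gts = np.empty(len(roster), dtype=np.int8)
            dhffc = np.full(len(roster), np.nan)
            has_dhffc = "DHFFC" in vf.header.formats
            for j, sample in enumerate(roster):
                call = rec.samples[sample]
                gts[j] = _gt_to_code(call.get("GT"))
                if has_dhffc:
                    v = call.get("DHFFC")
                    if v is not None:
                        dhffc[j] = v
            records.append(
                SVRecord(
                    id=rec.id or f"sv{i}",
                    chrom=rec.chrom,
                    start=start,
                    end=end,
                    svtype=svtype,
                    genotypes=gts,
                    dhffc=dhffc if has_dhffc else None,
                )
            )
    return records, roster


_CODE_TO_GT = {
    int(Genotype.MISSING): (None, None),
    int(Genotype.HOM_REF): (0, 0),
    int(Genotype.HET): (0, 1),
    int(Genotype.HOM_ALT): (1, 1),
}


def write_sv_vcf(records: Iterable[SVRecord], roster: list, path: str,
                 contig_lengths: Optional[dict] = None) -> None:
    """Write records as VCF 4.2 with symbolic ALT alleles.

    Masked genotypes are emitted as ``./.``. The header is fully
    deterministic (no timestamps), so writing identical records yields
    byte-identical files.
    """
    records = list(records)
    for rec in records:
        if rec.genotypes.shape[0] != len(roster):
            raise ValueError(f"record {rec.id}: sample count does not match roster")
    header = pysam.VariantHeader()
    header.add_meta("INFO", items=[("ID", "SVTYPE"), ("Number", "1"), ("Type", "String"),
                                   ("Description", "Type of structural variant")])
    header.add_meta("INFO", items=[("ID", "END"), ("Number", "1"), ("Type", "Integer"),
                                   ("Description", "End position of the variant")])
    header.add_meta("FORMAT", items=[("ID", "GT"), ("Number", "1"), ("Type", "String"),
                                     ("Description", "Genotype")])
    header.add_meta("FORMAT", items=[("ID", "DHFFC"), ("Number", "1"), ("Type", "Float"),
                                     ("Description",
                                      "Depth fold-change relative to flanking regions")])
    if contig_lengths is None:
        contig_lengths = {}
        for rec in records:
            contig_lengths[rec.chrom] = max(contig_lengths.get(rec.chrom, 0), rec.end + 1)
    for chrom in contig_lengths:
        header.contigs.add(chrom, length=contig_lengths[chrom])
    for sample in roster:
        header.add_sample(sample)
    with pysam.VariantFile(path, "w", header=header) as out:
        for rec in records:
            vrec = out.new_record(
                contig=rec.chrom,
                start=rec.start,
                stop=rec.end if rec.svtype != "BND" else rec.start + 1,
                alleles=("N", f"<{rec.svtype}>"),
                id=rec.id,
            )
            vrec.info["SVTYPE"] = rec.svtype
            for j, sample in enumerate(roster):
                vrec.samples[sample]["GT"] = _CODE_TO_GT[int(rec.genotypes[j])]
                if rec.dhffc is not None and np.isfinite(rec.dhffc[j]):
                    vrec.samples[sample]["DHFFC"] = round(float(rec.dhffc[j]), 4)
            out.write(vrec)


def read_bed(path: str) -> list:
    """Read BED3/BED4+ into :class:`BedFeature` (intervals kept verbatim).

    Lines with start >= end are rejected with a warning; duplicates are
    preserved as distinct features.
    """
    feats: list = []
    n_rejected = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                n_rejected += 1
                logger.warning("BED line with start >= end rejected: %s", line)
                continue
            name = parts[3] if len(parts) > 3 else None
            feats.append(BedFeature(chrom, start, end, name))
    if n_rejected:
        logger.warning("%d malformed BED lines rejected from %s", n_rejected, path)
    return feats


def write_bed(features: Iterable[BedFeature], path: str) -> None:
    with open(path, "w") as out:
        for f in features:
            if f.name is None:
                out.write(f"{f.chrom}\t{f.start}\t{f.end}\n")
            else:
                out.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.name}\n")


_UTR5_TYPES = {"five_prime_UTR", "five_prime_utr"}
_UTR3_TYPES = {"three_prime_UTR", "three_prime_utr"}


def read_gff3(path: str) -> list:
    """Parse GFF3 gene models (gene -> mRNA -> exon/CDS/UTR) via gffutils.

    Coordinates are converted to 0-based half-open. Orphan exons are
    skipped with a warning; a CDS outside its transcript's exon union is a
    hard error.
    """
    db = gffutils.create_db(
        path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models: list = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        transcripts = []
        for tx in db.children(gene, featuretype=("mRNA", "transcript"), order_by="start"):
            exons, cds, utr5, utr3 = [], [], [], []
            for child in db.children(tx, order_by="start"):
                ivl = (child.start - 1, child.end)
                if child.featuretype == "exon":
                    exons.append(ivl)
                elif child.featuretype == "CDS":
                    cds.append(ivl)
                elif child.featuretype in _UTR5_TYPES:
                    utr5.append(ivl)
                elif child.featuretype in _UTR3_TYPES:
                    utr3.append(ivl)
            if not exons:
                logger.warning("transcript %s has no exons; skipped", tx.id)
                continue
            transcripts.append(
                Transcript(transcript_id=tx.id, exons=sorted(exons),
                           cds=sorted(cds), utr5=sorted(utr5), utr3=sorted(utr3))
            )
        model = GeneModel(
            gene_id=gene.id,
            chrom=gene.seqid,
            start=gene.start - 1,
            end=gene.end,
            strand=gene.strand,
            transcripts=transcripts,
        )
        model.validate()  # raises on CDS outside exon union
        models.append(model)
    return models


def read_population_map(path: str) -> PopulationPanel:
    """Read a 2/3-column TSV ``sample<TAB>group[<TAB>exclude-flag]``.

    Any non-empty third column marks the sample as excluded (e.g. an F1
    hybrid). A sample assigned to two different groups is a hard error.
    """
    assignment: dict = {}
    excluded: set = set()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            sample, group = parts[0], parts[1]
            flag = parts[2] if len(parts) > 2 else ""
            if flag.strip():
                excluded.add(sample)
                continue
            if sample in assignment and assignment[sample] != group:
                raise ValueError(f"sample {sample} assigned to two groups")
            assignment[sample] = group
    return PopulationPanel(assignment=assignment, excluded=frozenset(excluded))


@dataclass
class DepthTrack:
    """Per-chromosome mean-depth segments (bedGraph-like, half-open).

    Segments must be sorted and non-overlapping within each chromosome;
    overlap is a hard error because a per-base mean would be ambiguous.
    """

    segments: dict  # chrom -> (starts, ends, depths) numpy arrays

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DepthTrack":
        segments = {}
        for chrom, grp in df.groupby("chrom", sort=False):
            grp = grp.sort_values("start")
            starts = grp["start"].to_numpy(dtype=np.int64)
            ends = grp["end"].to_numpy(dtype=np.int64)
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping depth segments on {chrom}")
            segments[chrom] = (starts, ends, grp["depth"].to_numpy(dtype=float))
        return cls(segments=segments)

    def chrom_extent(self, chrom: str) -> tuple:
        starts, ends, _ = self.segments[chrom]
        return int(starts[0]), int(ends[-1])

    def mean_depth(self, chrom: str, start: int, end: int) -> float:
        """Length-weighted mean depth over [start, end)."""
        if chrom not in self.segments:
            raise KeyError(f"chromosome {chrom} absent from depth track")
        starts, ends, depths = self.segments[chrom]
        lo, hi = self.chrom_extent(chrom)
        if start < lo or end > hi:
            raise ValueError(f"interval {chrom}:{start}-{end} outside track extent")
        i = np.searchsorted(ends, start, side="right")
        j = np.searchsorted(starts, end, side="left")
        if i >= j:
            return float("nan")
        ov = np.minimum(ends[i:j], end) - np.maximum(starts[i:j], start)
        covered = float(ov.sum())
        if covered <= 0:
            return float("nan")
        return float((ov * depths[i:j]).sum() / covered)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for chrom, (starts, ends, depths) in self.segments.items():
            rows.append(pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": ends, "depth": depths}))
        return pd.concat(rows, ignore_index=True)

    def write(self, path: str) -> None:
        self.to_dataframe().to_csv(path, sep="\t", header=False, index=False)


def read_depth_track(path: str) -> DepthTrack:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "depth"], comment="#")
    return DepthTrack.from_dataframe(df)
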