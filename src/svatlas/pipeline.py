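"""End-to-end orchestration: filter -> annotate -> overlaps -> popgen ->
domestication scan -> enrichment, with every summary table written as TSV
plus a machine-readable run manifest.

The report bundle mirrors the summary surfaces of an SV atlas study:
filter funnel, per-type size and MAF summaries, density windows,
annotation category proportions, repeat and constrained-element overlap
tables, per-site F_ST tables, the candidate scan and the enrichment
tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import annotate as ann
from . import domestication as dom
from . import enrichment as enr
from . import intervals as itv
from . import io as io_
from . import popgen
from .filtering import FilterConfig, run_filter_cascade

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    vcf: str
    pops: str
    gff: str
    genome: str  # TSV: chrom, length[, whitelist flag]
    gaps_bed: Optional[str] = None
    repeats_bed: Optional[str] = None
    gerp_bed: Optional[str] = None
    depth_track: Optional[str] = None
    high_depth_bed: Optional[str] = None
    domain_map: Optional[str] = None  # TSV: term, gene
    term_map: Optional[str] = None    # TSV: term, gene
    outdir: str = "svatlas_out"
    seed: int = 0
    updown_bp: int = 5000
    quantile: float = 0.95
    comparisons: Optional[list] = None  # [(farmed, wild), ...]; default: farmed vs all
    farmed_group: str = "FARMED"
    filter: FilterConfig = field(default_factory=FilterConfig)
    density_window_bp: int = 1_000_000
    density_high: int = 80
    density_low: int = 10
    enrich_p: float = 0.05
    enrich_q: float = 0.05
    n_pca_components: int = 10

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        fc = FilterConfig(**raw.pop("filter", {}))
        comparisons = raw.pop("comparisons", None)
        if comparisons is not None:
            comparisons = [tuple(c) for c in comparisons]
        return cls(filter=fc, comparisons=comparisons, **raw)


def _read_genome(path: str) -> tuple:
    lengths, whitelist = {}, set()
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or not parts[0]:
                continue
            lengths[parts[0]] = int(parts[1])
            if len(parts) < 3 or parts[2] not in ("0", "false", "False"):
                whitelist.add(parts[0])
    return lengths, whitelist


def _read_term_map(path: str) -> dict:
    out: dict = {}
    df = pd.read_csv(path, sep="\t", header=None, names=["term", "gene"],
                     comment="#", dtype=str)
    for term, grp in df.groupby("term"):
        out[term] = set(grp["gene"])
    return out


def _config_hash(cfg: PipelineConfig) -> str:
    def default(o):
        if isinstance(o, frozenset):
            return sorted(o)
        return str(o)
    payload = json.dumps(asdict(cfg), sort_keys=True, default=default)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and write the report bundle under ``cfg.outdir``.

    Returns the manifest dict (also written as manifest.json). Optional
    inputs (GERP BED, repeat BED, domain/term maps, expression) simply
    skip their stages, which the manifest records.
    """
    os.makedirs(cfg.outdir, exist_ok=True)
    manifest: dict = {
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "stages": {},
        "skipped": [],
        "outputs": {},
    }

    def out_path(name: str) -> str:
        manifest["outputs"][name] = name
        return os.path.join(cfg.outdir, name)

    # ------------------------------------------------------------- load
    records, roster = io_.read_sv_vcf(cfg.vcf)
    panel = io_.read_population_map(cfg.pops)
    genes = io_.read_gff3(cfg.gff)
    chrom_lengths, whitelist = _read_genome(cfg.genome)
    gaps = [f.interval for f in io_.read_bed(cfg.gaps_bed)] if cfg.gaps_bed else []
    manifest["stages"]["input_records"] = len(records)
    manifest["stages"]["n_samples"] = len(roster)

    # ----------------------------------------------------------- filter
    fc = cfg.filter
    if fc.chrom_whitelist is None and whitelist:
        fc = FilterConfig(**{**asdict(fc), "chrom_whitelist": frozenset(whitelist)})
    track = io_.read_depth_track(cfg.depth_track) if cfg.depth_track else None
    high_depth = ([f.interval for f in io_.read_bed(cfg.high_depth_bed)]
                  if cfg.high_depth_bed else [])
    filtered, report = run_filter_cascade(
        records, fc, gaps=gaps, high_depth=high_depth, depth_track=track)
    funnel = pd.DataFrame(
        [{"step": s.step, "input": s.n_input, "removed": s.n_removed,
          "surviving": s.n_surviving} for s in report.steps])
    funnel.to_csv(out_path("filter_funnel.tsv"), sep="\t", index=False)
    manifest["stages"]["filtered_records"] = len(filtered)
    manifest["stages"]["genotypes_masked"] = report.n_genotypes_masked

    # ----------------------------------------------------- summaries
    stats = [popgen.allele_stats(r) for r in filtered]
    summaries = popgen.size_maf_summaries(filtered, stats)
    with open(out_path("size_maf_summary.json"), "w") as fh:
        json.dump(summaries, fh, indent=2, sort_keys=True)
    density = popgen.sv_density(
        [r for r in filtered if r.chrom in chrom_lengths], chrom_lengths,
        window_bp=cfg.density_window_bp, high=cfg.density_high, low=cfg.density_low)
    pd.DataFrame([asdict(w) for w in density]).to_csv(
        out_path("density_windows.tsv"), sep="\t", index=False)

    # ----------------------------------------------------- annotation
    annotations = ann.annotate_all(filtered, genes, updown_bp=cfg.updown_bp)
    pd.DataFrame(
        [{"sv_id": a.sv_id, "gene_id": a.gene_id or "",
          "consequence": a.consequence, "impact": a.impact}
         for a in annotations]
    ).to_csv(out_path("annotations.tsv"), sep="\t", index=False)
    cats = ann.summarize_categories(annotations)
    pd.DataFrame(
        sorted(cats["term_proportions"].items()),
        columns=["consequence", "proportion"],
    ).to_csv(out_path("annotation_categories.tsv"), sep="\t", index=False)
    all_gene_ids = [g.gene_id for g in genes]
    affected, associated, background = ann.aggregate_gene_sets(
        annotations, all_gene_ids)
    manifest["stages"]["n_annotations"] = len(annotations)
    manifest["stages"]["n_high_impact_genes"] = len(affected)

    # ------------------------------------------------------- overlaps
    if cfg.repeats_bed:
        repeats = io_.read_bed(cfg.repeats_bed)
        rep_feats = [io_.BedFeature(f.chrom, f.start, f.end,
                                    f"{f.name or 'repeat'}|{i}")
                     for i, f in enumerate(repeats)]
        pairs = itv.overlap_join(filtered, rep_feats, min_bp=1, min_recip=0.5)
        pd.DataFrame(
            [{"sv_id": p.query_id, "repeat": p.subject_id, "chrom": p.chrom,
              "overlap_bp": p.overlap_bp, "frac_sv": p.frac_query,
              "frac_repeat": p.frac_subject} for p in pairs]
        ).to_csv(out_path("repeat_overlaps.tsv"), sep="\t", index=False)
        manifest["stages"]["repeat_overlap_pairs"] = len(pairs)
    else:
        manifest["skipped"].append("repeat_overlap")

    if cfg.gerp_bed:
        gerp = io_.read_bed(cfg.gerp_bed)
        summary = itv.summarize_gerp_overlap(filtered, gerp, min_bp=1)
        overlapping_ids = set(summary.per_sv)
        high_sv_ids = {a.sv_id for a in annotations if a.impact == "HIGH"}
        k_sub = len(overlapping_ids & high_sv_ids)
        test = enr.subset_proportion_test(
            k_sub, len(overlapping_ids), len(high_sv_ids), len(filtered)) \
            if overlapping_ids else None
        payload = {
            "n_svs_overlapping": summary.n_svs_overlapping,
            "n_elements_overlapped": summary.n_elements_overlapped,
            "element_length_mean": summary.element_length_mean,
            "element_length_sd": summary.element_length_sd,
            "overlap_mean": summary.overlap_mean,
            "overlap_sd": summary.overlap_sd,
            "high_impact_in_subset": k_sub,
            "chi_square_p": None if test is None else test.p,
            "chi_square_statistic": None if test is None else test.statistic,
        }
        with open(out_path("gerp_summary.json"), "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
        manifest["stages"]["gerp_overlapping_svs"] = summary.n_svs_overlapping
    else:
        manifest["skipped"].append("gerp_overlap")

    # --------------------------------------------------------- popgen
    analysed = [r for r in filtered if r.svtype != "BND"]
    kept_samples = [s for s in roster if s in panel.assignment]
    pca_records = [r.copy() for r in analysed]
    keep_idx = np.array([i for i, s in enumerate(roster)
                         if s in panel.assignment], dtype=int)
    for r in pca_records:
        r.genotypes = r.genotypes[keep_idx]
        r.dhffc = None
    n_comp = min(cfg.n_pca_components, len(kept_samples))
    coords, evr = popgen.genotype_pca(pca_records, kept_samples, n_comp)
    coords.to_csv(out_path("pca_coordinates.tsv"), sep="\t")

    groups = sorted(set(panel.assignment.values()))
    comparisons = cfg.comparisons or [
        (cfg.farmed_group, g) for g in groups if g != cfg.farmed_group]
    fst_table = popgen.wc_fst_table(analysed, panel, roster, comparisons)
    fst_table.to_csv(out_path("fst.tsv"), sep="\t", index=False,
                     float_format="%.6g")
    manifest["stages"]["fst_comparisons"] = len(comparisons)

    # ----------------------------------------------------------- scan
    scan_cfg = dom.ScanConfig(comparisons=list(comparisons),
                              quantile=cfg.quantile)
    candidates = dom.candidate_scan(fst_table, scan_cfg)
    records_by_id = {r.id: r for r in analysed}
    cand_table = dom.candidate_gene_table(candidates, annotations,
                                          records_by_id=records_by_id)
    cand_table.to_csv(out_path("candidates.tsv"), sep="\t", index=False,
                      float_format="%.6g")
    manifest["stages"]["n_candidates"] = len(candidates)
    manifest["stages"]["n_candidate_genes"] = len(
        dom.unique_candidate_genes(candidates))

    # ----------------------------------------------------- enrichment
    if cfg.domain_map:
        domain_map = _read_term_map(cfg.domain_map)
        rows = enr.fisher_domain_enrichment(affected, background, domain_map)
        pd.DataFrame([asdict(r) for r in rows]).to_csv(
            out_path("domain_enrichment.tsv"), sep="\t", index=False,
            float_format="%.6g")
        manifest["stages"]["domain_terms_tested"] = len(rows)
    else:
        manifest["skipped"].append("domain_enrichment")

    if cfg.term_map:
        term_map = _read_term_map(cfg.term_map)
        universe = associated & set(all_gene_ids)
        query = affected & universe
        if universe and query:
            rows = enr.geneset_enrichment(query, universe, term_map,
                                          cfg.enrich_p, cfg.enrich_q)
            pd.DataFrame([asdict(r) for r in rows]).to_csv(
                out_path("geneset_enrichment.tsv"), sep="\t", index=False,
                float_format="%.6g")
            manifest["stages"]["geneset_terms_tested"] = len(rows)
        else:
            manifest["skipped"].append("geneset_enrichment")
    else:
        manifest["skipped"].append("geneset_enrichment")

    with open(os.path.join(cfg.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
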