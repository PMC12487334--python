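"""Farmed-vs-wild candidate scan.

A domestication candidate is an SV that (i) sits in the top quantile
(default 5%) of per-site F_ST values in EVERY farmed-vs-wild comparison
and (ii) shows the same non-zero sign of allele-frequency change
(farmed - wild) in every comparison. Running each wild group separately
and intersecting avoids confounding by the structure among the wild
groups themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScanConfig",
    "CandidateSV",
    "top_quantile_set",
    "candidate_scan",
    "candidate_gene_table",
]


@dataclass
class ScanConfig:
    comparisons: list  # ordered (group1, group2); group1 shared (farmed)
    quantile: float = 0.95
    min_defined: int = 20

    def __post_init__(self) -> None:
        if not (0 < self.quantile < 1):
            raise ValueError("quantile must lie in (0, 1)")
        g1s = {c[0] for c in self.comparisons}
        if len(g1s) != 1:
            raise ValueError("group1 must be identical across comparisons")


@dataclass
class CandidateSV:
    sv_id: str
    theta: dict  # comparison -> theta
    delta_af: dict  # comparison -> farmed minus wild AF
    direction: int  # shared sign of delta_af
    mean_theta: float
    gene_ids: list = field(default_factory=list)
    regulatory_overlaps: list = field(default_factory=list)


def _comparison_label(g1: str, g2: str) -> str:
    return f"{g1}_vs_{g2}"


def top_quantile_set(fst_table: pd.DataFrame, comparison: str,
                     quantile: float = 0.95, min_defined: int = 20) -> tuple:
    """IDs of records with theta >= the empirical ``quantile`` of the
    defined thetas of one comparison (linear-interpolation quantile;
    threshold membership inclusive, so threshold ties are all kept).

    Returns (id set, threshold).
    """
    t = fst_table[(fst_table["comparison"] == comparison) & fst_table["defined"]]
    thetas = t["theta"].to_numpy(dtype=float)
    if thetas.size < min_defined:
        raise ValueError(
            f"only {thetas.size} defined theta values for {comparison}; "
            f"need >= {min_defined}")
    threshold = float(np.quantile(thetas, quantile, method="linear"))
    ids = set(t.loc[t["theta"] >= threshold, "sv_id"])
    return ids, threshold


def candidate_scan(fst_table: pd.DataFrame, config: ScanConfig) -> list:
    """Intersect the per-comparison top sets, then keep SVs whose
    delta_af sign is identical and non-zero in all comparisons. Output is
    sorted by mean theta, descending (ties broken by id)."""
    labels = [_comparison_label(g1, g2) for g1, g2 in config.comparisons]
    top_sets = {}
    for label in labels:
        ids, _thr = top_quantile_set(fst_table, label, config.quantile,
                                     config.min_defined)
        top_sets[label] = ids
    shared = set.intersection(*top_sets.values()) if top_sets else set()

    sub = fst_table[fst_table["sv_id"].isin(shared)]
    theta_by = sub.pivot_table(index="sv_id", columns="comparison",
                               values="theta", aggfunc="first")
    daf_by = sub.pivot_table(index="sv_id", columns="comparison",
                             values="delta_af", aggfunc="first")
    candidates: list = []
    for sv_id in shared:
        dafs = [daf_by.loc[sv_id, lbl] for lbl in labels]
        signs = {int(np.sign(d)) for d in dafs}
        if len(signs) != 1 or 0 in signs:
            continue
        thetas = {lbl: float(theta_by.loc[sv_id, lbl]) for lbl in labels}
        candidates.append(CandidateSV(
            sv_id=sv_id,
            theta=thetas,
            delta_af={lbl: float(d) for lbl, d in zip(labels, dafs)},
            direction=signs.pop(),
            mean_theta=float(np.mean(list(thetas.values()))),
        ))
    candidates.sort(key=lambda c: (-c.mean_theta, c.sv_id))
    return candidates


def candidate_gene_table(candidates: Sequence[CandidateSV],
                         annotations: Sequence,
                         records_by_id: Optional[dict] = None,
                         expression: Optional[pd.DataFrame] = None,
                         regulatory: Optional[Sequence] = None) -> pd.DataFrame:
    """Join candidates with their annotated genes (unique per SV),
    optionally z-scaled tissue expression columns (expression indexed by
    gene) and regulatory-element overlaps (>= 1 bp).

    A candidate with no annotation appears with an empty gene list.
    """
    genes_by_sv: dict = {}
    for a in annotations:
        if a.gene_id is not None:
            genes_by_sv.setdefault(a.sv_id, set()).add(a.gene_id)

    reg_by_sv: dict = {}
    if regulatory is not None and records_by_id is not None:
        from .intervals import overlap_join
        cand_records = [records_by_id[c.sv_id] for c in candidates
                        if c.sv_id in records_by_id]
        for pair in overlap_join(cand_records, regulatory, min_bp=1):
            reg_by_sv.setdefault(pair.query_id, []).append(pair.subject_id)

    zexpr = None
    if expression is not None:
        mu = expression.mean(axis=1)
        sd = expression.std(axis=1, ddof=0).replace(0, 1.0)
        zexpr = expression.sub(mu, axis=0).div(sd, axis=0)

    rows = []
    for c in candidates:
        genes = sorted(genes_by_sv.get(c.sv_id, set()))
        c.gene_ids = genes
        c.regulatory_overlaps = sorted(reg_by_sv.get(c.sv_id, []))
        row = {
            "sv_id": c.sv_id,
            "mean_theta": c.mean_theta,
            "direction": c.direction,
            "genes": ",".join(genes),
            "n_genes": len(genes),
            "regulatory_overlaps": ",".join(c.regulatory_overlaps),
        }
        for lbl, th in c.theta.items():
            row[f"theta_{lbl}"] = th
        for lbl, d in c.delta_af.items():
            row[f"delta_af_{lbl}"] = d
        if zexpr is not None and genes:
            present = [g for g in genes if g in zexpr.index]
            if present:
                for tissue in zexpr.columns:
                    row[f"zexpr_{tissue}"] = float(zexpr.loc[present, tissue].mean())
        rows.append(row)
    return pd.DataFrame(rows)


def unique_candidate_genes(candidates: Sequence[CandidateSV]) -> set:
    out: set = set()
    for c in candidates:
        out.update(c.gene_ids)
    return out
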