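"""Filter cascade: thresholds at their exact boundaries, per-base
oracles for the depth computations, and truth recovery on the simulator."""

import numpy as np
import pandas as pd
import pytest

from svatlas.filtering import (
    FilterConfig,
    compute_dhffc,
    compute_high_depth_regions,
    filter_ac_callrate,
    filter_sites,
    mask_genotypes_dhffc,
    run_filter_cascade,
)
from svatlas.io import DepthTrack
from svatlas.model import GenomicInterval, Genotype
from tests.conftest import make_record


def track_from(rows):
    return DepthTrack.from_dataframe(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "depth"]))


class TestHighDepthRegions:
    def test_uniform_low_depth_yields_nothing(self):
        t = track_from([("chr1", i * 100, (i + 1) * 100, 20) for i in range(10)])
        assert compute_high_depth_regions(t, 100) == []

    def test_adjacent_passing_segments_merge(self):
        t = track_from([("chr1", 0, 100, 50), ("chr1", 100, 200, 150),
                        ("chr1", 200, 300, 150), ("chr1", 300, 400, 80)])
        assert compute_high_depth_regions(t, 100) == \
            [GenomicInterval("chr1", 100, 300)]

    def test_threshold_is_strict(self):
        t = track_from([("chr1", 0, 100, 100.0)])
        assert compute_high_depth_regions(t, 100) == []

    def test_matches_per_base_oracle(self, rng):
        edges = np.sort(rng.choice(np.arange(1, 10_000), 60, replace=False))
        edges = np.concatenate([[0], edges, [10_000]])
        depths = rng.uniform(0, 200, edges.size - 1)
        t = track_from([("chr1", int(s), int(e), float(d))
                        for s, e, d in zip(edges[:-1], edges[1:], depths)])
        regions = compute_high_depth_regions(t, 100)
        per_base = np.zeros(10_000, dtype=bool)
        for s, e, d in zip(edges[:-1], edges[1:], depths):
            per_base[s:e] = d > 100
        oracle = []
        i = 0
        while i < per_base.size:
            if per_base[i]:
                j = i
                while j < per_base.size and per_base[j]:
                    j += 1
                oracle.append(GenomicInterval("chr1", i, j))
                i = j
            else:
                i += 1
        assert regions == oracle


class TestDHFFC:
    def test_uniform_depth_gives_one(self):
        t = track_from([("chr1", 0, 10_000, 30)])
        assert compute_dhffc(t, GenomicInterval("chr1", 4000, 5000)) == \
            pytest.approx(1.0)

    def test_half_depth_inside(self):
        t = track_from([("chr1", 0, 1000, 20), ("chr1", 1000, 2000, 10),
                        ("chr1", 2000, 3000, 20)])
        assert compute_dhffc(t, GenomicInterval("chr1", 1000, 2000)) == \
            pytest.approx(0.5)

    def test_matches_length_weighted_oracle(self, rng):
        edges = np.sort(rng.choice(np.arange(1, 10_000), 40, replace=False))
        edges = np.concatenate([[0], edges, [10_000]])
        depths = rng.uniform(1, 100, edges.size - 1)
        per_base = np.repeat(depths, np.diff(edges))
        t = track_from([("chr1", int(s), int(e), float(d))
                        for s, e, d in zip(edges[:-1], edges[1:], depths)])
        # SV near chromosome start -> unequal flank lengths after clipping
        sv = GenomicInterval("chr1", 600, 2400)
        got = compute_dhffc(t, sv, flank_bp=1000)
        inside = per_base[600:2400].mean()
        flank = np.concatenate([per_base[0:600], per_base[2400:3400]]).mean()
        assert got == pytest.approx(inside / flank, rel=1e-12)

    def test_sv_outside_track_is_error(self):
        t = track_from([("chr1", 0, 1000, 30)])
        with pytest.raises(ValueError):
            compute_dhffc(t, GenomicInterval("chr1", 500, 1500))


class TestSiteFilters:
    def test_bnd_removed_as_translocation(self):
        cfg = FilterConfig(chrom_whitelist={"chr1"})
        recs = [make_record(rid="b", svtype="BND", start=10, end=11)]
        survivors, reasons, _ = filter_sites(recs, cfg)
        assert survivors == [] and reasons == {"b": "translocation"}

    def test_one_bp_gap_overlap_removes(self):
        cfg = FilterConfig()
        gap = GenomicInterval("chr1", 199, 300)
        recs = [make_record(rid="d", start=100, end=200)]  # overlaps gap by 1 bp
        survivors, reasons, _ = filter_sites(recs, cfg, gaps=[gap])
        assert reasons == {"d": "gap_overlap"}
        # touching (0 bp) does not remove
        survivors, reasons, _ = filter_sites(
            recs, cfg, gaps=[GenomicInterval("chr1", 200, 300)])
        assert len(survivors) == 1

    def test_matches_predicate_oracle(self, rng):
        cfg = FilterConfig(chrom_whitelist={"chr1", "chr2"})
        gaps = [GenomicInterval("chr1", 1000, 2000)]
        hds = [GenomicInterval("chr2", 5000, 6000)]
        recs = []
        for i in range(200):
            chrom = ["chr1", "chr2", "scaffold"][int(rng.integers(3))]
            start = int(rng.integers(0, 9000))
            svtype = ["DEL", "DUP", "INV", "BND"][int(rng.integers(4))]
            recs.append(make_record(rid=f"r{i}", chrom=chrom, start=start,
                                    end=start + 500, svtype=svtype))
        survivors, _, _ = filter_sites(recs, cfg, gaps=gaps, high_depth=hds)

        def keep(r):
            if r.chrom not in cfg.chrom_whitelist or r.svtype == "BND":
                return False
            for ivl in gaps + hds:
                if r.chrom == ivl.chrom and r.start < ivl.end and ivl.start < r.end:
                    return False
            return True

        assert [r.id for r in survivors] == [r.id for r in recs if keep(r)]


class TestDhffcMasking:
    cfg = FilterConfig()

    def run_one(self, svtype, gt, dhffc):
        rec = make_record(rid="x", svtype=svtype, genotypes=[gt],
                          dhffc=[dhffc])
        out, masked = mask_genotypes_dhffc([rec], self.cfg)
        return int(out[0].genotypes[0])

    @pytest.mark.parametrize("dhffc,expected", [
        (0.5, Genotype.HET),        # consistent with a real deletion
        (0.7, Genotype.HET),        # boundary retained (strict >)
        (0.71, Genotype.MISSING),   # inconsistent -> masked
    ])
    def test_deletion_thresholds(self, dhffc, expected):
        assert self.run_one("DEL", Genotype.HET, dhffc) == expected

    @pytest.mark.parametrize("dhffc,expected", [
        (1.3, Genotype.HET),        # boundary retained (strict <)
        (1.29, Genotype.MISSING),
        (1.6, Genotype.HET),
    ])
    def test_duplication_thresholds(self, dhffc, expected):
        assert self.run_one("DUP", Genotype.HET, dhffc) == expected

    @pytest.mark.parametrize("dhffc,expected", [
        (0.7, Genotype.HOM_ALT),    # band endpoints excluded
        (1.3, Genotype.HOM_ALT),
        (1.0, Genotype.MISSING),
        (0.4, Genotype.HOM_ALT),
    ])
    def test_inversion_band(self, dhffc, expected):
        assert self.run_one("INV", Genotype.HOM_ALT, dhffc) == expected

    def test_non_carriers_and_missing_never_masked(self):
        assert self.run_one("DEL", Genotype.HOM_REF, 1.0) == Genotype.HOM_REF
        assert self.run_one("DEL", Genotype.MISSING, 1.0) == Genotype.MISSING

    def test_absent_dhffc_retains_genotype(self):
        rec = make_record(rid="x", svtype="DEL",
                          genotypes=[Genotype.HET], dhffc=[np.nan])
        out, masked = mask_genotypes_dhffc([rec], self.cfg)
        assert int(out[0].genotypes[0]) == Genotype.HET and masked == {}

    def test_alt_alleles_never_increase(self, rng):
        recs = [make_record(rid=f"r{i}", svtype="DEL",
                            genotypes=rng.integers(-1, 3, 30),
                            dhffc=rng.uniform(0, 2, 30)) for i in range(50)]
        before = sum(np.sum(r.genotypes == 1) + 2 * np.sum(r.genotypes == 2)
                     for r in recs)
        out, _ = mask_genotypes_dhffc(recs, self.cfg)
        after = sum(np.sum(r.genotypes == 1) + 2 * np.sum(r.genotypes == 2)
                    for r in out)
        assert after <= before


class TestAcCallrate:
    cfg = FilterConfig()

    def test_ac_boundary(self):
        # a single heterozygote among 10 samples: AC=1 <= 2 -> removed
        rec = make_record(rid="x", genotypes=[1] + [0] * 9)
        survivors, reasons, _ = filter_ac_callrate([rec], self.cfg)
        assert reasons == {"x": "low_allele_count"}
        rec = make_record(rid="y", genotypes=[1, 2] + [0] * 8)  # AC=3
        survivors, _, _ = filter_ac_callrate([rec], self.cfg)
        assert len(survivors) == 1

    def test_call_rate_boundary_inclusive(self):
        # 8 of 10 called -> rate exactly 0.80 survives
        rec = make_record(rid="x", genotypes=[1, 2, 1, 2, 1, 0, 0, 0, -1, -1])
        survivors, _, _ = filter_ac_callrate([rec], self.cfg)
        assert len(survivors) == 1
        rec = make_record(rid="y", genotypes=[1, 2, 1, 2, 1, 0, 0, -1, -1, -1])
        _, reasons, _ = filter_ac_callrate([rec], self.cfg)
        assert reasons == {"y": "low_call_rate"}

    def test_matches_counting_oracle(self, rng):
        recs = [make_record(rid=f"r{i}", genotypes=rng.integers(-1, 3, 25))
                for i in range(100)]
        survivors, _, _ = filter_ac_callrate(recs, self.cfg)

        def keep(r):
            g = r.genotypes
            ac = int((g == 1).sum() + 2 * (g == 2).sum())
            return ac > 2 and (g != -1).mean() >= 0.8

        assert [r.id for r in survivors] == [r.id for r in recs if keep(r)]


class TestCascade:
    def test_no_violations_is_identity(self):
        cfg = FilterConfig(chrom_whitelist={"chr1"})
        recs = [make_record(rid=f"r{i}", start=i * 1000, end=i * 1000 + 100,
                            genotypes=[1, 2, 1, 2, 0, 0, 0, 0, 0, 0],
                            dhffc=[0.5] * 10) for i in range(5)]
        survivors, report = run_filter_cascade(recs, cfg)
        assert [r.id for r in survivors] == [r.id for r in recs]
        assert all(s.n_removed == 0 for s in report.steps)

    def test_cascade_is_idempotent_and_order_independent(self, sim_bundle):
        cfg_sim, ref, cohort = sim_bundle
        cfg = FilterConfig(chrom_whitelist=ref.whitelist)
        surv1, _ = run_filter_cascade(cohort.records, cfg, gaps=ref.gaps,
                                      depth_track=ref.depth)
        surv2, rep2 = run_filter_cascade(surv1, cfg, gaps=ref.gaps,
                                         depth_track=ref.depth)
        assert [r.id for r in surv2] == [r.id for r in surv1]
        assert sum(s.n_removed for s in rep2.steps) == 0
        perm = list(reversed(cohort.records))
        surv3, _ = run_filter_cascade(perm, cfg, gaps=ref.gaps,
                                      depth_track=ref.depth)
        assert {r.id for r in surv3} == {r.id for r in surv1}

    def test_truth_recovery_on_simulated_cohort(self, sim_bundle):
        """Removal reasons and masked-genotype sets equal the simulator's
        truth labels exactly (thresholds are deterministic)."""
        cfg_sim, ref, cohort = sim_bundle
        cfg = FilterConfig(chrom_whitelist=ref.whitelist)
        survivors, report = run_filter_cascade(
            cohort.records, cfg, gaps=ref.gaps, depth_track=ref.depth)
        truth = cohort.truth.set_index("sv_id")
        assert set(report.removal_reasons) == \
            set(truth.index[truth.expected_removed])
        for rid, reason in report.removal_reasons.items():
            assert reason == truth.loc[rid, "expected_reason"]
        roster = cohort.roster
        got_masked = {rid: {roster[j] for j in idx}
                      for rid, idx in report.masked_genotypes.items()}
        for rid, expected in truth["masked_samples"].items():
            exp = set(expected.split(";")) if expected else set()
            if truth.loc[rid, "expected_reason"] in (
                    "", "low_allele_count", "low_call_rate"):
                # records reaching the masking stage
                assert got_masked.get(rid, set()) == exp, rid
        report.validate_telescoping()
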