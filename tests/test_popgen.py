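"""Allele statistics, Weir–Cockerham F_ST against two independent
oracles, SV density binning and genotype PCA."""

import numpy as np
import pandas as pd
import pytest

from svatlas.model import PopulationPanel
from svatlas.popgen import (
    allele_stats,
    fst_ratio_of_averages,
    genotype_pca,
    size_maf_summaries,
    sv_density,
    wc_fst,
    wc_fst_table,
)
from svatlas.simulate import simulate_frequency_cohort
from tests.conftest import make_record


def wc_components_oracle(g1, g2):
    """Direct scalar transcription of the Weir & Cockerham (1984)
    two-population variance-component formulas for diploids."""
    def summarize(g):
        g = [int(x) for x in g if x >= 0]
        n = len(g)
        p = sum(g) / (2 * n)
        h = sum(1 for x in g if x == 1) / n
        return n, p, h

    n1, p1, h1 = summarize(g1)
    n2, p2, h2 = summarize(g2)
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                       / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


def two_group_setup(g1, g2):
    roster = [f"a{i}" for i in range(len(g1))] + [f"b{i}" for i in range(len(g2))]
    panel = PopulationPanel({**{f"a{i}": "P1" for i in range(len(g1))},
                             **{f"b{i}": "P2" for i in range(len(g2))}})
    rec = make_record(rid="x", genotypes=list(g1) + list(g2))
    return rec, panel, roster


class TestAlleleStats:
    def test_arithmetic(self):
        rec = make_record(genotypes=[2] * 4 + [0] * 6)
        s = allele_stats(rec)
        assert (s.af, s.maf, s.ac, s.an) == (0.4, 0.4, 8, 20)
        rec = make_record(genotypes=[1] * 10)
        s = allele_stats(rec)
        assert s.af == 0.5 and s.maf == 0.5

    def test_missing_excluded_and_undefined_flagged(self):
        rec = make_record(genotypes=[1, 2, -1, -1])
        s = allele_stats(rec)
        assert (s.ac, s.an, s.call_rate) == (3, 4, 0.5)
        s = allele_stats(make_record(genotypes=[-1, -1]))
        assert not s.defined

    def test_maf_bounded(self, rng):
        for _ in range(50):
            s = allele_stats(make_record(genotypes=rng.integers(-1, 3, 30)))
            if s.defined:
                assert 0 <= s.maf <= 0.5


class TestWeirCockerham:
    def test_fixed_difference_is_one(self):
        rec, panel, roster = two_group_setup([2] * 10, [0] * 10)
        assert wc_fst(rec, panel, roster, "P1", "P2").theta == pytest.approx(1.0)

    def test_identical_groups_not_positive(self):
        g = [0] * 4 + [1] * 4 + [2] * 2
        rec, panel, roster = two_group_setup(g, g)
        res = wc_fst(rec, panel, roster, "P1", "P2")
        assert res.theta <= 0
        assert res.delta_af == pytest.approx(0.0)

    def test_monomorphic_site_is_undefined(self):
        rec, panel, roster = two_group_setup([0] * 5, [0] * 5)
        assert wc_fst(rec, panel, roster, "P1", "P2").theta is None

    def test_spec_example_matches_oracle(self):
        g1 = [0] * 4 + [1] * 4 + [2] * 2
        g2 = [0] * 8 + [1] * 2
        rec, panel, roster = two_group_setup(g1, g2)
        res = wc_fst(rec, panel, roster, "P1", "P2")
        a, b, c = wc_components_oracle(g1, g2)
        assert res.theta == pytest.approx(a / (a + b + c), abs=1e-12)
        assert res.delta_af == pytest.approx(0.4 - 0.1)

    def test_matches_formula_oracle_on_random_sites(self, rng):
        """Vectorized implementation equals the scalar transcription of
        the published component formulas to 1e-6 on 1,000 random sites."""
        n1, n2 = 18, 31
        g1s = rng.integers(0, 3, size=(1000, n1))
        g2s = rng.integers(0, 3, size=(1000, n2))
        recs, panels = [], None
        roster = [f"a{i}" for i in range(n1)] + [f"b{i}" for i in range(n2)]
        panel = PopulationPanel({**{f"a{i}": "P1" for i in range(n1)},
                                 **{f"b{i}": "P2" for i in range(n2)}})
        recs = [make_record(rid=f"s{i}", genotypes=list(g1s[i]) + list(g2s[i]))
                for i in range(1000)]
        table = wc_fst_table(recs, panel, roster, [("P1", "P2")])
        for i in range(1000):
            a, b, c = wc_components_oracle(g1s[i], g2s[i])
            row = table.iloc[i]
            if a + b + c == 0:
                assert not row["defined"]
            else:
                assert abs(row["theta"] - a / (a + b + c)) < 1e-6

    def test_balding_nichols_recovery_small(self, rng):
        """Ratio-of-averages recovers the simulated divergence."""
        recs, roster, panel, _ = simulate_frequency_cohort(
            2000, {"P1": 50, "P2": 50}, 0.1, rng)
        table = wc_fst_table(recs, panel, roster, [("P1", "P2")])
        assert fst_ratio_of_averages(table) == pytest.approx(0.1, abs=0.02)


class TestDensity:
    def test_strict_thresholds(self):
        recs = [make_record(rid=f"r{i}", start=1000 + i, end=2000 + i)
                for i in range(81)]
        wins = sv_density(recs, {"chr1": 2_000_000})
        assert wins[0].count == 81 and wins[0].klass == "HIGH"
        wins = sv_density(recs[:80], {"chr1": 2_000_000})
        assert wins[0].klass == "NORMAL"
        assert wins[1].count == 0 and wins[1].klass == "LOW"

    def test_matches_binning_oracle(self, rng):
        chrom_lengths = {"chr1": 5_500_000, "chr2": 3_000_000}
        recs = []
        for i in range(500):
            chrom = "chr1" if rng.random() < 0.6 else "chr2"
            start = int(rng.integers(0, chrom_lengths[chrom] - 100))
            recs.append(make_record(rid=f"r{i}", chrom=chrom, start=start,
                                    end=start + 100))
        wins = sv_density(recs, chrom_lengths)
        oracle = {}
        for r in recs:
            oracle[(r.chrom, r.start // 1_000_000)] = \
                oracle.get((r.chrom, r.start // 1_000_000), 0) + 1
        for w in wins:
            assert w.count == oracle.get((w.chrom, w.start // 1_000_000), 0)
        assert sum(w.count for w in wins) == len(recs)
        # trailing partial window flagged
        assert [w for w in wins if w.chrom == "chr1"][-1].partial


def test_size_maf_summaries():
    recs = [make_record(rid="a", start=0, end=100),
            make_record(rid="b", start=0, end=200),
            make_record(rid="c", start=0, end=400)]
    s = size_maf_summaries(recs)
    assert s["overall"]["mean_length"] == pytest.approx(233.3333, abs=1e-3)
    assert s["overall"]["median_length"] == 200
    assert s["per_type"]["DEL"]["count"] == 3
    stats = [allele_stats(make_record(genotypes=[1] + [0] * 49)),
             allele_stats(make_record(genotypes=[1] * 20 + [0] * 30))]
    s = size_maf_summaries(recs[:2], stats)
    assert s["maf"]["n_rare"] == 1


class TestPCA:
    def test_identical_samples_coincide(self):
        recs = [make_record(rid=f"r{i}", genotypes=[g, g, 0, 2])
                for i, g in enumerate([1, 2, 0, 1, 2])]
        coords, _ = genotype_pca(recs, ["s1", "s2", "s3", "s4"], n_components=2)
        np.testing.assert_allclose(coords.loc["s1"], coords.loc["s2"], atol=1e-12)

    def test_explained_variance_properties(self, rng):
        recs = [make_record(rid=f"r{i}", genotypes=rng.integers(0, 3, 12))
                for i in range(40)]
        _, evr = genotype_pca(recs, [f"s{i}" for i in range(12)], n_components=5)
        assert np.all(np.diff(evr) <= 1e-12)
        assert evr.sum() <= 1 + 1e-9

    def test_two_populations_separate_on_pc1(self, rng):
        recs, roster, panel, _ = simulate_frequency_cohort(
            500, {"P1": 30, "P2": 30}, 0.2, rng)
        coords, _ = genotype_pca(recs, roster, n_components=2)
        pc1 = coords["PC1"]
        m1 = pc1[[s for s in roster if s.startswith("P1")]].mean()
        m2 = pc1[[s for s in roster if s.startswith("P2")]].mean()
        spread = pc1.std()
        assert abs(m1 - m2) > spread  # clear group separation

    def test_too_many_components_is_error(self):
        recs = [make_record(genotypes=[0, 1, 2])]
        with pytest.raises(ValueError):
            genotype_pca(recs, ["a", "b", "c"], n_components=5)
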