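"""Consequence rules on constructed gene models, plus planted-term
recovery on the simulator's fixtures."""

import numpy as np
import pytest

from svatlas.annotate import (
    aggregate_gene_sets,
    classify_sv,
    select_curation_samples,
    summarize_categories,
)
from svatlas.model import Genotype
from tests.conftest import make_gene, make_record


def terms_of(annotations, gene_id=None):
    return {a.consequence for a in annotations
            if gene_id is None or a.gene_id == gene_id}


class TestClassification:
    def test_intronic_deletion(self):
        gene = make_gene()
        sv = make_record(start=220, end=280)  # inside intron (200, 300)
        anns = classify_sv(sv, [gene])
        assert terms_of(anns) == {"intron_variant"}
        assert all(a.impact == "MODIFIER" for a in anns)

    def test_exon_loss_keeps_partial_transcript(self):
        # deletion removing 4 of 5 exons is exon loss, not ablation
        exons = [(i * 1000, i * 1000 + 100) for i in range(5)]
        gene = make_gene(exons=exons)
        sv = make_record(start=950, end=4150)
        terms = terms_of(classify_sv(sv, [gene]))
        assert "exon_loss_variant" in terms
        assert "transcript_ablation" not in terms

    def test_whole_transcript_deletion_is_ablation(self):
        gene = make_gene()
        sv = make_record(start=50, end=700)
        assert "transcript_ablation" in terms_of(classify_sv(sv, [gene]))

    def test_fusion_strand_rules(self):
        a = make_gene("gA", exons=((1000, 1100), (1500, 1600)), strand="+")
        b = make_gene("gB", exons=((5000, 5100), (5500, 5600)), strand="+")
        sv = make_record(svtype="INV", start=1300, end=5300)
        anns = classify_sv(sv, [a, b])
        assert "gene_fusion" in terms_of(anns, "gA")
        assert "gene_fusion" in terms_of(anns, "gB")
        assert all(a_.impact == "HIGH" for a_ in anns
                   if a_.consequence == "gene_fusion")
        # opposite strands -> bidirectional fusion
        b_rev = make_gene("gB", exons=((5000, 5100), (5500, 5600)), strand="-")
        anns = classify_sv(sv, [a, b_rev])
        assert "bidirectional_gene_fusion" in terms_of(anns, "gA")

    @pytest.mark.parametrize("end,expect_frameshift", [
        (1050, True),   # 50 bp of CDS removed: 50 % 3 != 0
        (1051, False),  # 51 bp removed: in-frame
    ])
    def test_frameshift_requires_non_triplet_cds_loss(self, end, expect_frameshift):
        gene = make_gene(exons=((1000, 1300),), cds=((1000, 1300),))
        sv = make_record(start=900, end=end)
        terms = terms_of(classify_sv(sv, [gene]))
        assert ("frameshift_variant" in terms) == expect_frameshift

    def test_duplication_containing_exon_is_moderate(self):
        gene = make_gene()
        sv = make_record(svtype="DUP", start=250, end=450)  # contains exon (300,400)
        anns = classify_sv(sv, [gene])
        assert "exon_region_variant" in terms_of(anns)
        assert "HIGH" not in {a.impact for a in anns}

    def test_inversion_spanning_gene(self):
        gene = make_gene()
        sv = make_record(svtype="INV", start=50, end=700)
        assert "transcript_inversion" in terms_of(classify_sv(sv, [gene]))

    def test_utr_breakpoints(self):
        gene = make_gene(exons=((100, 200), (300, 400)), cds=((150, 200), (300, 350)),
                         utr5=((100, 150),), utr3=((350, 400),))
        sv = make_record(start=120, end=140)
        assert "5_prime_UTR_variant" in terms_of(classify_sv(sv, [gene]))
        sv = make_record(start=360, end=380)
        assert "3_prime_UTR_variant" in terms_of(classify_sv(sv, [gene]))

    @pytest.mark.parametrize("strand,side,expected", [
        ("+", "before", "upstream_gene_variant"),
        ("+", "after", "downstream_gene_variant"),
        ("-", "before", "downstream_gene_variant"),
        ("-", "after", "upstream_gene_variant"),
    ])
    def test_updownstream_is_strand_aware(self, strand, side, expected):
        gene = make_gene(strand=strand, exons=((10_000, 10_100), (10_500, 10_600)))
        sv = make_record(start=8000, end=8100) if side == "before" \
            else make_record(start=12_000, end=12_100)
        assert terms_of(classify_sv(sv, [gene])) == {expected}

    def test_intergenic_iff_no_gene_within_window(self):
        gene = make_gene(exons=((10_000, 10_100), (10_500, 10_600)))
        sv = make_record(start=4000, end=5000)  # gap exactly 5000 -> nearby
        assert terms_of(classify_sv(sv, [gene], updown_bp=5000)) == \
            {"upstream_gene_variant"}
        sv = make_record(start=3999, end=4999)  # gap 5001 -> intergenic
        anns = classify_sv(sv, [gene], updown_bp=5000)
        assert terms_of(anns) == {"intergenic_region"}
        assert anns[0].gene_id is None

    def test_every_sv_gets_an_annotation(self):
        # breakpoint in a non-coding exon region matches no specific rule
        gene = make_gene(exons=((100, 200),), cds=())
        sv = make_record(start=150, end=1000)
        anns = classify_sv(sv, [gene])
        assert anns and terms_of(anns) == {"gene_variant"}

    def test_enlarging_keeps_containment_terms(self):
        gene = make_gene(exons=[(i * 1000, i * 1000 + 100) for i in range(5)])
        small = make_record(start=950, end=2150)
        large = make_record(start=900, end=3150)
        assert "exon_loss_variant" in terms_of(classify_sv(small, [gene]))
        assert "exon_loss_variant" in terms_of(classify_sv(large, [gene]))


def test_planted_consequences_recovered(sim_bundle):
    """Simulator-planted intronic / exon-deleting / gene-spanning SVs all
    receive their planted term."""
    _, ref, cohort = sim_bundle
    truth = cohort.truth.set_index("sv_id")
    planted = truth[truth.expected_term != ""]
    assert len(planted) > 0
    by_chrom = {}
    for g in ref.genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    recs = {r.id: r for r in cohort.records}
    for rid, row in planted.iterrows():
        anns = classify_sv(recs[rid], by_chrom.get(row["chrom"], []))
        assert row["expected_term"] in {a.consequence for a in anns}, rid


def test_aggregate_gene_sets():
    from svatlas.annotate import SVAnnotation
    anns = [SVAnnotation("s1", "g1", "exon_loss_variant", "HIGH"),
            SVAnnotation("s1", "g1", "intron_variant", "MODIFIER"),
            SVAnnotation("s2", "g2", "upstream_gene_variant", "MODIFIER"),
            SVAnnotation("s3", None, "intergenic_region", "MODIFIER")]
    affected, associated, background = aggregate_gene_sets(anns, ["g1", "g2", "g3"])
    assert affected == {"g1"}
    assert associated == {"g1", "g2"}
    assert background == {"g2", "g3"}
    # no HIGH annotations -> empty affected, full background
    affected, _, background = aggregate_gene_sets(anns[2:], ["g1", "g2"])
    assert affected == set() and background == {"g1", "g2"}


def test_summarize_categories_normalizes():
    from svatlas.annotate import SVAnnotation
    anns = [SVAnnotation("s1", "g1", "intron_variant", "MODIFIER"),
            SVAnnotation("s1", "g2", "gene_fusion", "HIGH"),
            SVAnnotation("s2", "g3", "intron_variant", "MODIFIER")]
    s = summarize_categories(anns)
    assert s["n_annotations"] == 3 and s["n_svs"] == 2
    assert sum(s["term_proportions"].values()) == pytest.approx(1.0)
    assert s["term_proportions"]["intron_variant"] == pytest.approx(2 / 3)
    assert s["cooccurrence"][frozenset({"intron_variant", "gene_fusion"})] == 1


class TestCurationSampling:
    roster = [f"s{i}" for i in range(20)]

    def test_quota_rule(self):
        g = [0] * 8 + [1] * 6 + [2] * 6
        rec = make_record(genotypes=g)
        chosen = select_curation_samples(rec, self.roster, seed=1)
        gts = [g[self.roster.index(s)] for s in chosen]
        assert len(chosen) == 7
        assert gts.count(0) == 2 and gts.count(1) == 2 and gts.count(2) == 3

    def test_shortfall_backfilled(self):
        g = [0] * 14 + [1] * 6  # no hom-alt available
        rec = make_record(genotypes=g)
        chosen = select_curation_samples(rec, self.roster, seed=1)
        assert len(chosen) == 7
        assert all(g[self.roster.index(s)] != Genotype.MISSING for s in chosen)

    def test_few_called_samples_returns_all(self):
        g = [0, 1, 2, -1, -1] + [-1] * 15
        rec = make_record(genotypes=g)
        assert len(select_curation_samples(rec, self.roster, seed=5)) == 3

    def test_seed_determinism(self):
        g = list(np.random.default_rng(0).integers(0, 3, 20))
        rec = make_record(genotypes=g)
        assert select_curation_samples(rec, self.roster, seed=42) == \
            select_curation_samples(rec, self.roster, seed=42)
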