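import numpy as np
import pytest

from svatlas.model import GeneModel, SVRecord, Transcript
from svatlas.simulate import SimConfig, simulate_cohort, simulate_reference


def make_record(rid="sv1", chrom="chr1", start=100, end=200, svtype="DEL",
                genotypes=(0, 1, 2), dhffc=None):
    return SVRecord(id=rid, chrom=chrom, start=start, end=end, svtype=svtype,
                    genotypes=np.array(genotypes, dtype=np.int8),
                    dhffc=None if dhffc is None else np.array(dhffc, float))


def make_gene(gene_id="geneA", chrom="chr1", strand="+", exons=((100, 200), (300, 400), (500, 600)),
              cds=None, utr5=None, utr3=None):
    exons = [tuple(e) for e in exons]
    if cds is None:
        cds = exons
    tx = Transcript(transcript_id=f"{gene_id}.t1", exons=exons, cds=list(cds),
                    utr5=list(utr5 or []), utr3=list(utr3 or []))
    return GeneModel(gene_id=gene_id, chrom=chrom, start=exons[0][0],
                     end=exons[-1][1], strand=strand, transcripts=[tx])


@pytest.fixture(scope="session")
def sim_bundle():
    """One full synthetic reference + cohort shared across the suite."""
    cfg = SimConfig(seed=3)
    ref = simulate_reference(cfg)
    cohort = simulate_cohort(cfg, ref)
    return cfg, ref, cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
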