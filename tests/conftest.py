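import numpy as np
import pytest

from lncweanflow.annotation_io import Annotation, Exon, GeneModel, TranscriptModel
from lncweanflow.simulate import SimulationConfig, simulate_annotation


def make_tx(tid, exons, strand="+", chrom="chr1", gene_id=None, biotype="unknown"):
    """Shorthand transcript builder: exons as (start, end) tuples."""
    return TranscriptModel(
        transcript_id=tid,
        gene_id=gene_id or f"g_{tid}",
        chrom=chrom,
        strand=strand,
        exons=[Exon(chrom, s, e) for s, e in exons],
        biotype=biotype,
    )


def make_annotation(*transcripts) -> Annotation:
    ann = Annotation()
    by_gene = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    for gid, txs in by_gene.items():
        ann.add_gene(GeneModel(gid, txs[0].chrom, txs[0].strand, txs, txs[0].biotype))
    return ann


def random_exon_chain(rng, chrom="chr1", lo=1_000, hi=40_000, max_exons=4):
    """Random sorted, non-overlapping exon chain for property tests."""
    n = int(rng.integers(1, max_exons + 1))
    pos = int(rng.integers(lo, hi))
    exons = []
    for _ in range(n):
        length = int(rng.integers(80, 500))
        exons.append((pos, pos + length - 1))
        pos += length + int(rng.integers(60, 800))
    return [Exon(chrom, s, e) for s, e in exons]


@pytest.fixture(scope="session")
def sim_cfg() -> SimulationConfig:
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def synthetic(sim_cfg):
    """One shared synthetic annotation with its manifest."""
    return simulate_annotation(sim_cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
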