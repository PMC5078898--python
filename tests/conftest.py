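import numpy as np
import pytest

from dipseq.genome import GeneModel, Genome, GenomicInterval, TagSet


@pytest.fixture
def genome():
    return Genome({"chr1": 2_000, "chr2": 5_000})


@pytest.fixture
def make_tags(genome):
    """Factory for small TagSets from {chrom: positions} dicts."""

    def _make(positions, assay="5hmC", condition="sham", sample_id="s1",
              gen=None):
        gen = gen or genome
        return TagSet(sample_id, assay, condition, gen,
                      {c: np.asarray(p, dtype=np.int64)
                       for c, p in positions.items()})

    return _make


@pytest.fixture
def simple_gene():
    return GeneModel("geneA", "chr2", "+", 100, 600,
                     (GenomicInterval("chr2", 100, 600),))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
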