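import numpy as np
import pytest

import ectomap as em


def make_tagset(genome, records):
    """records: iterable of (chrom, pos, strand)."""
    if not records:
        return em.TagSet(genome, np.array([], object), np.array([], int),
                         np.array([], "U1"))
    chrom, pos, strand = zip(*records)
    return em.TagSet(genome, list(chrom), list(pos), list(strand))


def make_intervals(triples, labels=None, scores=None, genome=None):
    """triples: iterable of (chrom, start, end)."""
    if not triples:
        return em.IntervalSet(np.array([], object), np.zeros(0, int),
                              np.zeros(0, int), genome=genome)
    chrom, start, end = zip(*triples)
    return em.IntervalSet(
        np.array(chrom, object), np.array(start), np.array(end),
        labels=np.array(labels, object) if labels is not None else None,
        scores=np.array(scores, float) if scores is not None else None,
        genome=genome,
    )


@pytest.fixture
def genome1k():
    return em.GenomeDef({"chr1": 1000})


@pytest.fixture
def genome10k():
    return em.GenomeDef({"chr1": 10_000})


@pytest.fixture(scope="session")
def small_landscape():
    """Scaled-down version of the default landscape: fast but still powered."""
    truth = em.acceptance_landscape(seed=3, scale=0.05)
    chip = em.simulate_tags(truth, "chip", replicate_seed=31)
    ctrl = em.simulate_tags(truth, "input", replicate_seed=32)
    return truth, chip, ctrl
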