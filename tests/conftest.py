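import numpy as np
import pytest

from atackit.alignments import Fragment, GenomeIndex


@pytest.fixture
def toy_genome():
    return GenomeIndex((("chr1", 100_000), ("chr2", 50_000)))


@pytest.fixture
def small_genome():
    return GenomeIndex((("chr1", 10_000),))


def make_fragments(spans, contig="chr1", strand="+"):
    return [Fragment(contig, s, e, strand) for s, e in spans]


@pytest.fixture
def frag_factory():
    return make_fragments


def simulate_background(seed, genome_length=100_000, rate=0.02, fraglen=100,
                        planted=None, contig="chr1"):
    """Poisson background fragments with an optional planted enriched region.

    ``planted`` is (start, end, multiplier); extra fragments are centered
    uniformly inside the region at (multiplier - 1) x background rate.
    """
    rng = np.random.default_rng(seed)
    n = rng.poisson(rate * genome_length)
    starts = rng.integers(0, genome_length - fraglen, n)
    frags = [Fragment(contig, int(s), int(s) + fraglen) for s in starts]
    if planted is not None:
        s0, e0, mult = planted
        extra = rng.poisson(rate * (mult - 1) * (e0 - s0))
        mids = rng.integers(s0, e0, extra)
        for m in mids:
            st = int(np.clip(m - fraglen // 2, 0, genome_length - fraglen))
            frags.append(Fragment(contig, st, st + fraglen))
    return frags
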