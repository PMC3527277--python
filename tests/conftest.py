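import numpy as np
import pytest

from mitoret.intervals import GenomicInterval, IntervalSet
from mitoret.simulate import SimulationConfig, simulate_experiment


def brute_force_overlap_pairs(a, b, min_bp=1):
    """O(n*m) all-against-all overlap oracle."""
    pairs = []
    for i, x in enumerate(a):
        for j, y in enumerate(b):
            if x.chrom != y.chrom:
                continue
            inter = min(x.end, y.end) - max(x.start, y.start)
            if inter >= min_bp:
                pairs.append((i, j))
    return pairs


def random_interval_set(rng, n, genome, max_width=2000):
    ivs = []
    chroms = list(genome)
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, genome[chrom] - max_width))
        width = int(rng.integers(1, max_width))
        ivs.append(GenomicInterval(chrom, start, start + width))
    return IntervalSet(ivs, genome=genome)


@pytest.fixture(scope="session")
def toy_genome():
    return {"chr2L": 1_000_000, "chr2R": 1_000_000, "chr3L": 1_000_000, "chr4": 1_000_000}


@pytest.fixture(scope="session")
def small_experiment():
    """A small but realistic two-condition simulation shared by the
    slower integration tests."""
    cfg = SimulationConfig(
        n_sites=300,
        depth=15_000,
        retained_fraction=0.1,
        contamination=0.05,
        seed=11,
    )
    control, mitotic, truth = simulate_experiment(cfg)
    return cfg, control, mitotic, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
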