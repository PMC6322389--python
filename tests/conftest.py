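import numpy as np
import pytest

from hetdimer_chip import (
    GenomicInterval,
    PeakSet,
    SignalTrack,
    SimConfig,
    generate_annotation,
    generate_sites,
)

REP_COLS = {
    "alpha1": ["alpha1_rep1", "alpha1_rep2"],
    "alpha2": ["alpha2_rep1", "alpha2_rep2"],
    "beta": ["beta_rep1", "beta_rep2"],
}
ASSAY_COLS = {
    "alpha_total": REP_COLS["alpha1"] + REP_COLS["alpha2"],
    "beta": REP_COLS["beta"],
}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_cfg():
    """A small, fast default simulation configuration."""
    return SimConfig(
        genome_length=3_000_000,
        n_genes=60,
        n_sites_per_isoform=60,
        depth_per_assay=500_000,
        seed=7,
    )


@pytest.fixture
def small_truth(small_cfg):
    ann = generate_annotation(small_cfg)
    peaks, truth = generate_sites(small_cfg, ann)
    return ann, peaks, truth


def random_peakset(rng, n, genome=100_000, width_range=(50, 500)):
    ivs, seen = [], set()
    while len(ivs) < n:
        start = int(rng.integers(0, genome - width_range[1]))
        width = int(rng.integers(*width_range))
        key = ("chr1", start, start + width)
        if key in seen:
            continue
        seen.add(key)
        ivs.append(GenomicInterval(*key, name=f"iv{len(ivs)}"))
    return PeakSet(ivs)


@pytest.fixture
def flat_track():
    """Uniform coverage of 2 per base over [0, 10000), 1e7 mapped reads."""
    return SignalTrack(
        {"chr1": (np.array([0]), np.array([10_000]), np.array([2.0]))},
        total_mapped_reads=1e7,
    )
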