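import numpy as np
import pytest

from chipmeta import (
    ChromSizes,
    CoverageTrack,
    FactorSpec,
    SimulationConfig,
    simulate_annotation,
    simulate_reads,
)


@pytest.fixture
def sizes_small():
    return ChromSizes({"chr1": 100_000})


@pytest.fixture
def sizes_10kb():
    return ChromSizes({"chr1": 10_000})


def make_track(sizes, bin_width=25, fill=0.0, total_reads=0, track_id="t"):
    values = {
        chrom: np.full(-(-length // bin_width), float(fill))
        for chrom, length in sizes.items()
    }
    return CoverageTrack(sizes, bin_width, values, total_reads=total_reads, track_id=track_id)


@pytest.fixture(scope="session")
def small_sim():
    """A compact simulated dataset shared by read-based unit tests."""
    config = SimulationConfig(
        seed=11,
        chrom_sizes={"chr1": 2_000_000},
        n_genes=120,
        gene_length=(1_500, 4_000),
        n_enhancers=80,
        n_super_enhancers=8,
        se_length=(5_000, 12_000),
        factors=[FactorSpec("factorA", frac_genes_bound=0.4, background_reads=20_000)],
    )
    sim = simulate_annotation(config)
    reads = simulate_reads(config, sim)
    return config, sim, reads
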