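import pytest

from tcrsort.demux import demultiplex_blocks
from tcrsort.jref import default_jref
from tcrsort.sim import SimulationConfig, read_blocks, simulate_repertoire


@pytest.fixture(scope="session")
def jref():
    return default_jref()


@pytest.fixture(scope="session")
def clean_truth():
    """Two-donor, error-free, chimera-free ground truth."""
    cfg = SimulationConfig(
        n_donors=2, clones_per_sample=40, cells_per_sample=4000,
        reads_per_population=20_000, chimera_rate=0.0, seq_error_rate=0.0, seed=101,
    )
    return simulate_repertoire(cfg)


@pytest.fixture(scope="session")
def clean_blocks(clean_truth):
    return list(read_blocks(clean_truth))


@pytest.fixture(scope="session")
def clean_bins(clean_truth, clean_blocks):
    bins, stats = demultiplex_blocks(
        ((b.seq, b.count) for b in clean_blocks), clean_truth.scheme
    )
    return bins, stats


@pytest.fixture(scope="session")
def noisy_truth():
    """Ground truth with chimeric swapping and sequencing errors enabled."""
    cfg = SimulationConfig(
        n_donors=2, clones_per_sample=40, cells_per_sample=4000,
        reads_per_population=20_000, chimera_rate=0.02, seq_error_rate=0.002, seed=102,
    )
    return simulate_repertoire(cfg)
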