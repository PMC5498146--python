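import numpy as np
import pytest

import minimeta as mm


@pytest.fixture(scope="session")
def reference_sim() -> mm.SimulatedCommunity:
    """The canonical 8-genome simulated community (documented seed)."""
    return mm.simulate_community(mm.reference_scenario())


@pytest.fixture(scope="session")
def reference_binning(reference_sim):
    """Default-pipeline binning of the reference community."""
    return mm.bin_contigs(reference_sim.coverage, reference_sim.contig_lengths)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def supplement_patterns() -> tuple[np.ndarray, np.ndarray]:
    """Presence vectors of the worked two-contig example: both present in 8
    sub-samples, Y-only in 1, X-only in 2, neither in 6 (17 total)."""
    x = np.array([1] * 8 + [0] * 1 + [1] * 2 + [0] * 6)
    y = np.array([1] * 8 + [1] * 1 + [0] * 2 + [0] * 6)
    return x, y
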