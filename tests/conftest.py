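import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from decayscan import SimulationConfig, simulate_dataset
from decayscan.io import TranscriptAnnotation

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_reads(rows, sample_id="s1"):
    """Read-interval frame from (chrom, start, end, strand) tuples."""
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
    frame["sample_id"] = sample_id
    return frame


@pytest.fixture
def toy_tx():
    return TranscriptAnnotation("txA", "chr1", 100, 110, "+")


@pytest.fixture(scope="session")
def small_dataset():
    """A small but fully featured simulated experiment (both phases)."""
    config = SimulationConfig(
        n_transcripts=80,
        length_range=(300, 1200),
        mean_depth=400,
        seed=42,
    )
    return simulate_dataset(config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
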