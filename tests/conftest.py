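import numpy as np
import pytest

from plasmacna.synthetic_cohort import SimConfig

SMALL_GENOME = [
    ("chr1", 150_000_000),
    ("chr2", 130_000_000),
    ("chr3", 120_000_000),
    ("chr4", 100_000_000),
]

TINY_GENOME = [("chr1", 50_000_000), ("chr2", 40_000_000)]


#: event structure scaled to the reduced genome (same bins-per-event
#: scale as the default 2.9-Gb configuration)
SMALL_EVENTS = dict(n_cna_events=(4, 8), event_length=(5_000_000, 40_000_000))


@pytest.fixture
def small_config():
    """Reduced four-chromosome genome, event sizes scaled to fit."""
    return SimConfig(n_patients=8, genome=list(SMALL_GENOME), seed=123, **SMALL_EVENTS)


@pytest.fixture
def noiseless_config():
    return SimConfig(
        n_patients=8, genome=list(SMALL_GENOME), noise_sd=0.0, seed=123, **SMALL_EVENTS
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
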