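import os

os.environ.setdefault("MPLBACKEND", "Agg")

import numpy as np
import pandas as pd
import pytest

from tilewave import SimParams, simulate_array


@pytest.fixture(scope="session")
def spike_array_3mb():
    """3 Mb gapped array with 30 triangular spike-ins (seed 7)."""
    params = SimParams(
        genome_length=3_000_000, gap_fraction=0.3, mean_gap_length=1000, n_peaks=30
    )
    return simulate_array(params, seed=7)


@pytest.fixture(scope="session")
def null_array_2mb():
    """2 Mb fully tiled null array (seed 1)."""
    params = SimParams(genome_length=2_000_000, gap_fraction=0.0, n_peaks=0)
    probes, _ = simulate_array(params, seed=1)
    return probes


@pytest.fixture
def tiny_probes():
    """Six probes on two chromosomes with a gap and one overlap pair."""
    return pd.DataFrame(
        {
            "chrom": ["chr1"] * 4 + ["chr2"] * 2,
            "start": [0, 38, 200, 300, 0, 100],
            "end": [50, 88, 250, 350, 50, 150],
            "red": [10.0, 12.0, 9.0, 11.0, 8.0, 7.0],
            "green": [10.0, 10.0, 10.0, 10.0, 10.0, 10.0],
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
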