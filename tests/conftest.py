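import warnings

import numpy as np
import pandas as pd
import pytest

from heterosis3d.matrix_ops import BinTable, ContactMatrix
from heterosis3d.simulate import SimulationConfig, make_heterosis_trio, simulate_trio
from heterosis3d.workflow import analyze_trio


@pytest.fixture(scope="session")
def default_bundle():
    """Standard synthetic trio: 2 chroms x 200 bins at 100 kb."""
    return simulate_trio(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_results(default_bundle):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return analyze_trio(default_bundle)


@pytest.fixture(scope="session")
def preset_bundle():
    """Preset trio with boosted F1 trans contacts, split TADs, net B-to-A shifts."""
    return make_heterosis_trio(seed=0)


@pytest.fixture(scope="session")
def preset_results(preset_bundle):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return analyze_trio(preset_bundle)


def single_chrom_bins(n, resolution=100_000, chrom="chr1"):
    return BinTable.from_chrom_sizes({chrom: n * resolution}, resolution)


def symmetric_matrix(bins, rng, low=1, high=20):
    n = bins.n_bins
    a = rng.integers(low, high, size=(n, n)).astype(float)
    counts = np.triu(a) + np.triu(a, 1).T
    return ContactMatrix(bins, counts, state="raw")


def track_from_labels(labels, sample, resolution=100_000, chrom="chr1"):
    """Build a CompartmentTrack directly from a label vector."""
    from heterosis3d.compartments import CompartmentTrack

    n = len(labels)
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.arange(n) * resolution,
            "end": (np.arange(n) + 1) * resolution,
            "bin_id": np.arange(n),
            "pc1": [np.nan if l == "masked" else (1.0 if l == "A" else -1.0) for l in labels],
            "label": list(labels),
        }
    )
    return CompartmentTrack(sample=sample, df=df)
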