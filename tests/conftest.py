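import os
import tempfile

# keep hypothesis' on-disk caches out of the working tree
os.environ.setdefault(
    "HYPOTHESIS_STORAGE_DIRECTORY",
    os.path.join(tempfile.gettempdir(), "hypothesis"))

import numpy as np
import pytest
from hypothesis import settings

from fragscreen.pubchem_keys import default_key_table
from fragscreen.synthetic import BenchmarkSpec, generate_benchmark

# keep property tests reproducible and the working tree free of a
# hypothesis example database
settings.register_profile("fragscreen", database=None, derandomize=True,
                          deadline=None)
settings.load_profile("fragscreen")

#: Small molecules (all <= 8 heavy atoms) used for exhaustive
#: fingerprint cross-checks against brute-force oracles.
SMALL_MOLECULES = [
    "C", "CC", "CCN", "CCO", "C1CC1", "c1ccccc1", "CC(C)O", "CC(=O)N",
    "C1CCCC1", "CC#N", "OCC(N)C", "CSC", "CC=CC", "NC(=O)CO", "C1CCOC1",
    "CN(C)C=O",
]


@pytest.fixture(scope="session")
def key_table():
    return default_key_table()


@pytest.fixture(scope="session")
def bench_small():
    """A 4-target, 10:1 decoy-ratio benchmark with full planted signal."""
    return generate_benchmark(
        BenchmarkSpec(n_targets=4, actives_per_target=5, decoy_ratio=10,
                      signal_strength=1.0, seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
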