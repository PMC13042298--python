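import sys
from pathlib import Path

import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))   # make oracles importable

from recland import simdata

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_layout():
    """2 LGs of 5 Mb at 5 cM/Mb with 2 inversions, deterministic."""
    spec = simdata.LayoutSpec(n_lg=2, lg_length_bp=5_000_000, n_inversions=2,
                              inversion_size_bp=(500_000, 1_500_000), seed=101)
    return simdata.simulate_genome(spec)


@pytest.fixture(scope="session")
def small_family(small_layout):
    cfg = simdata.SimConfig(n_offspring=30, markers_per_lg=80, seed=102)
    return simdata.simulate_family(small_layout, cfg)


@pytest.fixture(scope="session")
def study_layout():
    """5 LGs / 6 inversions layout mirroring the two-family study design."""
    spec = simdata.LayoutSpec(n_lg=5, lg_length_bp=10_000_000, n_inversions=6,
                              seed=7)
    return simdata.simulate_genome(spec)
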