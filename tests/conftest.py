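import numpy as np
import pytest

from gaitglove.glove_io import default_layout
from gaitglove.synthetic import SyntheticSpec, simulate_runs


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture(scope="session")
def layout19(layout):
    return layout.subset(layout.relevant19)


@pytest.fixture(scope="session")
def small_cohort():
    """3 subjects x 4 runs, default generator parameters, fixed seed."""
    spec = SyntheticSpec(n_subjects=3, n_runs=4, seed=11)
    runs, truth = simulate_runs(spec)
    return runs, truth


@pytest.fixture(scope="session")
def clean_run():
    """Single noiseless, jitter-free run with its truth record."""
    spec = SyntheticSpec(
        n_subjects=1,
        n_runs=1,
        noise_sd=0.0,
        freq_jitter_sd=0.0,
        subject_loading_sd=0.0,
        seed=5,
    )
    runs, truth = simulate_runs(spec)
    return runs[0], truth.runs[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
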