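import numpy as np
import pytest

from parcelfuse import fit_fusion, make_world


@pytest.fixture(scope="session")
def small_world():
    """An easy, quickly fitted two-dataset world with near-hard ground truth."""
    specs = {
        "dsA": {"n_subjects": 3, "session_sizes": [6, 6], "kappa": 20.0, "n_runs": 2},
        "dsB": {"n_subjects": 3, "session_sizes": [6, 6], "kappa": 20.0, "n_runs": 2},
    }
    space, truth, datasets = make_world(
        width=8, height=8, K=4, smoothness=6.0, symmetric=True,
        dataset_specs=specs, seed=42,
    )
    return space, truth, datasets


@pytest.fixture(scope="session")
def fitted(small_world):
    space, truth, datasets = small_world
    model = fit_fusion(
        datasets, K=4, symmetric=True, space=space, n_starts=3, max_iter=80, seed=7
    )
    return space, truth, datasets, model


@pytest.fixture
def rng():
    return np.random.default_rng(0)
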