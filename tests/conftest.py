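import numpy as np
import pytest

import gaitprint as gp

#: Small sub-grid of the C range used where nested CV runs repeatedly;
#: conclusions about chance level / effect recovery do not depend on grid
#: resolution, only runtime does.
SMALL_GRID = 2.0 ** np.array([-5.0, 0.0, 5.0])
FAST_SVM = dict(tol=1e-3, max_iter=2000)


@pytest.fixture(scope="session")
def tiny_config() -> gp.CohortConfig:
    """4 subjects x 4 conditions x 3 trials — smallest design that still
    satisfies every task's fold rule (k=4)."""
    return gp.CohortConfig(n_subjects=4, n_conditions=4, n_trials=3, rng_seed=20)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return gp.generate_dataset(tiny_config)


@pytest.fixture(scope="session")
def tiny_features(tiny_dataset):
    recordings, _ = tiny_dataset
    return gp.process_dataset(recordings)


@pytest.fixture(scope="session")
def tiny_report(tiny_features):
    """A full nested-CV run on the tiny cohort (subject x footwear task)."""
    X, _, meta = tiny_features
    return gp.run_task(X, meta, "subject_x_footwear", seed=1, grid=SMALL_GRID, **FAST_SVM)
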