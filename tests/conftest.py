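import numpy as np
import pytest

import lbpstrat as L


@pytest.fixture(scope="session")
def blobs3():
    """Three well-separated Gaussian blobs in 2-D with known membership."""
    rng = np.random.default_rng(42)
    centers = np.array([[0.0, 0.0], [20.0, 0.0], [0.0, 20.0]])
    sizes = [60, 50, 40]
    points = np.vstack([rng.normal(c, 0.8, size=(n, 2))
                        for c, n in zip(centers, sizes)])
    truth = np.repeat(np.arange(3), sizes)
    return points, truth


@pytest.fixture(scope="session")
def small_cohort():
    """Default synthetic cohort, modest size; no embedding required."""
    cfg = L.default_config(n_participants=300, seed=5)
    return L.generate_cohort(cfg), cfg


@pytest.fixture(scope="session")
def default_recovery():
    """The pre-registered recovery experiment: default three-subgroup
    cohort (n=800, seed 0), grid search over k in 2..5 at the default
    UMAP setting.  Session-scoped because the embedding is expensive."""
    cfg = L.default_config(n_participants=800, seed=0)
    cohort = L.generate_cohort(cfg)
    result = L.stratify(cohort, seed=0)
    return cohort, result
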