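import numpy as np
import pandas as pd
import pytest

from somnoclust.synthetic import CohortSpec, default_regimes, generate_cohort


@pytest.fixture(scope="session")
def regimes3():
    return default_regimes(3, persistence=0.95)


@pytest.fixture(scope="session")
def cohort_10x42():
    """10 subjects x 42 days, 2 regimes, no missingness."""
    spec = CohortSpec(n_subjects=10, n_days=42,
                      regimes=default_regimes(2, persistence=0.9), seed=11)
    logs, truth = generate_cohort(spec)
    return spec, logs, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def blob_points():
    """Three well-separated 2-D blobs (for sweep/silhouette checks)."""
    from sklearn.datasets import make_blobs

    pts, labels = make_blobs(n_samples=150, centers=[(0, 0), (12, 0), (0, 12)],
                             cluster_std=0.6, random_state=5)
    return pts, labels
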