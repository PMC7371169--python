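import numpy as np
import pytest

import ethocv as ec


@pytest.fixture(scope="session")
def default_group():
    return ec.GroupProfile("g", size_scale=1.0)


@pytest.fixture(scope="session")
def small_cohort(default_group):
    """4 individuals, 6 s per behaviour, moderate individual effect."""
    script = ec.EthogramScript.uniform(6.0)
    return ec.generate_cohort(4, default_group, script,
                              individual_effect=0.8, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_cohort):
    windows = ec.dataset_windows(small_cohort)
    return ec.build_feature_dataset(windows)


@pytest.fixture(scope="session")
def two_cluster_dataset():
    """Two well-separated Gaussian blobs — a trivially separable problem."""
    rng = np.random.default_rng(0)
    n = 60
    X = np.vstack([rng.normal(0.0, 0.1, (n, 4)),
                   rng.normal(5.0, 0.1, (n, 4))])
    y = np.array(["walk"] * n + ["run"] * n, dtype=object)
    ind = np.array([f"i{j % 4}" for j in range(2 * n)], dtype=object)
    grp = np.array(["g"] * 2 * n, dtype=object)
    return ec.FeatureDataset(X, ("f0", "f1", "f2", "f3"), y, ind, grp)
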