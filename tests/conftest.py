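import numpy as np
import pytest

from metabopls.cohort import CohortConfig, MetaboliteSpec, MultipletDef
from metabopls.preprocess import BucketScheme, BucketTable, bucket_grid


def make_table(X, groups=None, fluid="urine", width=0.01, normalized=False):
    """Wrap a plain matrix in a BucketTable with a synthetic bucket grid."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    scheme = BucketScheme(
        region=(0.5 + p * width, 0.5), width=width, exclusions=(),
        reference=(0.5, width),
    )
    centers, mask = bucket_grid(scheme)
    if groups is None:
        groups = ["copd" if i < n // 2 else "control" for i in range(n)]
    return BucketTable(
        matrix=X,
        bucket_centers=centers,
        retained_mask=mask,
        normalized=normalized,
        scheme=scheme,
        sample_ids=[f"s{i:03d}" for i in range(n)],
        groups=list(groups),
        fluid=fluid,
    )


@pytest.fixture
def clean_render_config():
    """Noise-free, jitter-free acquisition settings for lineshape tests."""
    return CohortConfig(
        fluid="urine", ppm_min=0.0, ppm_max=2.0, points=20001,
        noise_sd=0.0, shift_jitter_sd=0.0, baseline_amplitude=0.0, seed=0,
    )


@pytest.fixture
def singlet_library():
    return [MetaboliteSpec("probe", (MultipletDef(1.0, "s"),), 1.0)]


@pytest.fixture
def small_urine_config():
    return CohortConfig(
        fluid="urine", n_copd=6, n_control=5, points=8192, seed=11
    )


def two_class_gaussian(n=40, p=10, delta=4.0, n_informative=3, seed=0):
    """Two balanced Gaussian classes separated by delta sigma on the first
    n_informative features."""
    rng = np.random.default_rng(seed)
    y = np.repeat([1.0, -1.0], n // 2)
    X = rng.normal(size=(n, p))
    X[:, :n_informative] += np.outer(y, np.full(n_informative, delta / 2.0))
    return X, y
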