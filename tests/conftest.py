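import numpy as np
import pytest

from perseclock import BetaMatrix, ClockConfig, SyntheticSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix():
    """3 samples x 4 loci with one missing entry."""
    values = np.array([
        [0.10, 0.20, 0.30, 0.40],
        [0.50, 0.60, 0.70, 0.80],
        [0.90, 0.15, 0.25, 0.35],
    ])
    mask = np.zeros_like(values, dtype=bool)
    mask[1, 2] = True
    return BetaMatrix(["s1", "s2", "s3"], ["cg01", "cg02", "cg03", "cg04"],
                      values, mask)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Fast cohort for training tests: 3x6x4 geometry, 72 loci, 400 samples."""
    spec = SyntheticSpec(n_samples=400, n_loci=72, n_informative=12, seed=7)
    bm, meta, truth = generate_cohort(spec, ClockConfig(channels=None))
    return bm, meta, truth


@pytest.fixture
def small_cfg():
    return ClockConfig(channels=None, block_rows=3, block_cols=6)
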