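import numpy as np
import pytest

import knnbench as kb


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def reference_best():
    """Packaged 12x16 best-score matrix (metrics x dataset/measure pairs)."""
    return kb.load_reference_best_scores()


@pytest.fixture(scope="session")
def reference_profiles(reference_best):
    return {m: reference_best.loc[m].to_numpy() for m in reference_best.index}


@pytest.fixture
def small_gaussian():
    spec = kb.DatasetSpec(
        kind="gaussian_float", n_samples=120, n_features=9, n_classes=2,
        separation=6.0, noise_sd=1.0, seed=7,
    )
    return kb.generate_dataset(spec)
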