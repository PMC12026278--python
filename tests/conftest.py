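import numpy as np
import pytest

import ilwdeeplab as I


@pytest.fixture(scope="session")
def tiny_spec():
    """Small 4-class scene spec used across tests."""
    return I.SceneSpec(seed=0, num_classes=4, canvas_side=64)


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory, tiny_spec):
    root = tmp_path_factory.mktemp("fixtures")
    return I.generate_dataset(tiny_spec, n_train=6, n_test=2, out_dir=root)


@pytest.fixture(scope="session")
def small_model():
    """5-class improved lightweight model with deterministic weights."""
    return I.ILWDeepLab(I.ilw_config(5, seed=0))


@pytest.fixture(scope="session")
def lw_103():
    return I.ILWDeepLab(I.lw_config(103, seed=0))


def random_labels(rng: np.random.Generator, shape, k: int) -> np.ndarray:
    return rng.integers(0, k, size=shape)
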