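import numpy as np
import pytest

import qmetric as qm


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_states():
    """Factory: n Haar-ish random normalized 4-amplitude states."""

    def make(n, seed=0):
        gen = np.random.default_rng(seed)
        v = gen.normal(size=(n, 4)) + 1j * gen.normal(size=(n, 4))
        return v / np.linalg.norm(v, axis=1, keepdims=True)

    return make


@pytest.fixture(scope="session")
def separable_table():
    """Small table whose classes are far apart relative to the noise."""
    spec = qm.SyntheticSpec(
        n_per_class=30, n_features=4, separation=8.0, cov_rank=2, noise_sd=0.5, seed=7
    )
    return qm.generate_two_class_table(spec)


@pytest.fixture(scope="session")
def trained_toy(separable_table):
    """A short training run on the separable toy: (train, test, params, trace)."""
    train_t, test_t = qm.split_train_test(separable_table, 0.6, seed=3)
    params0 = qm.init_params(train_t.n_features, seed=11)
    params, trace = qm.train(
        train_t, params0, qm.TrainConfig(steps=300, batch_size=10, seed=5)
    )
    return train_t, test_t, params, trace
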