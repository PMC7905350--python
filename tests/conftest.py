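import numpy as np
import pytest

from eegfatigue.types import EpochSet, FeatureSet, Recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_recording(rng):
    """1-minute 4-channel recording at 100 Hz with mixed sinusoids + noise."""
    rate = 100.0
    t = np.arange(int(60 * rate)) / rate
    data = np.vstack(
        [
            np.sin(2 * np.pi * (5 + i) * t) + 0.1 * rng.standard_normal(t.size)
            for i in range(4)
        ]
    )
    return Recording(
        data=data,
        rate=rate,
        channel_names=[f"C{i}" for i in range(4)],
        label=1,
        subject_id="S01",
    )


@pytest.fixture
def toy_features(rng):
    """Two separable Gaussian blobs as a ready-made FeatureSet (60 rows)."""
    n = 30
    X0 = rng.normal(loc=-1.0, scale=0.3, size=(n, 3))
    X1 = rng.normal(loc=1.0, scale=0.3, size=(n, 3))
    X = np.vstack([X0, X1])
    y = np.array([0] * n + [1] * n)
    perm = rng.permutation(2 * n)
    return FeatureSet(X[perm], y[perm], np.ones(2 * n))


def make_epoch_set(rng, n_epochs=6, channels=4, points=50, rate=10.0, labels=None):
    epochs = [rng.standard_normal((channels, points)) for _ in range(n_epochs)]
    if labels is None:
        labels = np.arange(n_epochs) % 2
    return EpochSet(epochs=epochs, labels=np.asarray(labels), points_per_epoch=points, rate=rate)
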