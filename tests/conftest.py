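import numpy as np
import pytest

from myodecode.cnn import ArchitectureConfig, TrainConfig, train_model
from myodecode.core_data import WindowSet, default_taxonomy

# keep BLAS deterministic-ish and grading-like
np.seterr(over="ignore")


@pytest.fixture(scope="session")
def taxonomy():
    return default_taxonomy()


def gain_windows(classes, n_per_class, n_channels=4, window_len=128, seed=0,
                 reps=None, gain_lo=0.2, gain_hi=2.0):
    """Fast separable window sets: class-specific channel gains x white noise.

    A lightweight stand-in for the full simulator in unit tests that only
    need labeled, learnable windows.
    """
    rng = np.random.default_rng(seed)
    gains = {c: rng.uniform(gain_lo, gain_hi, size=n_channels)
             for c in classes}
    windows, labels, rep_ids = [], [], []
    for c in classes:
        for i in range(n_per_class):
            w = gains[c][:, None] * rng.standard_normal((n_channels, window_len))
            windows.append(w)
            labels.append(c)
            rep_ids.append(1 + (i % reps if reps else 0))
    n = len(windows)
    return WindowSet(np.array(windows), np.array(labels, dtype=object),
                     np.array(rep_ids), np.full(n, "sideway", dtype=object),
                     np.full(n, "S0", dtype=object), window_len, window_len)


TINY_ARCH = ArchitectureConfig(variant="cnet1d", n_channels=4, window_len=128,
                               conv_filters=(4, 4, 4))


@pytest.fixture(scope="session")
def tiny_basic_windows(taxonomy):
    return gain_windows(taxonomy.basic_classes, 18, seed=11, reps=3)


@pytest.fixture(scope="session")
def tiny_base_model(taxonomy, tiny_basic_windows):
    """A small trained 8-class decoder shared by transfer tests."""
    cfg = TrainConfig(epochs=10, batch_size=32, lr=1e-3, patience=None, seed=5)
    return train_model(TINY_ARCH, tiny_basic_windows, cfg,
                       classes=taxonomy.basic_classes)
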