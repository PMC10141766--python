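import numpy as np
import pytest

import micompen as mc


@pytest.fixture(scope="session")
def small_recording():
    """8-trial synthetic recording with default signatures and artifacts."""
    rec, truth = mc.generate_recording(n_trials=8, seed=42)
    return rec, truth


@pytest.fixture(scope="session")
def small_feature_table(small_recording):
    rec, _ = small_recording
    epochs = mc.epoch(rec)
    return mc.extract_features(epochs)


def amari_index(P: np.ndarray) -> float:
    """Permutation/scale-invariant distance of P from a scaled permutation."""
    P = np.abs(np.asarray(P, dtype=float))
    n = P.shape[0]
    rows = (P / P.max(axis=1, keepdims=True)).sum(axis=1) - 1.0
    cols = (P / P.max(axis=0, keepdims=True)).sum(axis=0) - 1.0
    return float((rows.sum() + cols.sum()) / (2.0 * n * (n - 1)))


def ar1(n: int, pole: float, rng: np.random.Generator) -> np.ndarray:
    e = rng.standard_normal(n)
    x = np.empty(n)
    x[0] = e[0]
    for t in range(1, n):
        x[t] = pole * x[t - 1] + e[t]
    return x
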