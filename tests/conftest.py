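import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def brute_force_auc(scores, labels):
    """O(P*N) pair-counting AUC oracle: ties count one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def random_probability_rows(rng, n, m):
    """Random row-stochastic matrix."""
    x = rng.random((n, m)) + 1e-9
    return x / x.sum(axis=1, keepdims=True)
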