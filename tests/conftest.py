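import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix(rng):
    """10 genes x 6 samples of log-scale expression, no missing values."""
    genes = [f"g{i}" for i in range(10)]
    samples = [f"s{j}" for j in range(6)]
    return pd.DataFrame(
        rng.normal(8, 1, (10, 6)), index=genes, columns=samples
    )


def brute_force_es(weights, is_member, tau=1.0, es_mode="difference"):
    """Scalar re-implementation of the KS random walk, used as an oracle."""
    n = len(weights)
    members = [i for i in range(n) if is_member[i]]
    m = len(members)
    total = sum(abs(weights[i]) ** tau for i in members)
    running = 0.0
    d_pos = 0.0
    d_neg = 0.0
    for i in range(n):
        if is_member[i]:
            running += (abs(weights[i]) ** tau) / total if total > 0 else 1.0 / m
        else:
            running -= 1.0 / (n - m)
        d_pos = max(d_pos, running)
        d_neg = min(d_neg, running)
    if es_mode == "difference":
        return d_pos + d_neg
    return d_pos if d_pos >= -d_neg else d_neg
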