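import numpy as np
import pandas as pd
import pytest

from profilenet.datasets import SENNC_ITEMS, ResponseDataset
from profilenet.ising import IsingNetwork
from profilenet.simulate import default_three_class_config, generate_likert


@pytest.fixture(scope="session")
def three_class_data():
    """Reference synthetic survey: n=510, three classes, fixed seed."""
    data, truth = generate_likert(default_three_class_config(510, seed=1))
    return data, truth


@pytest.fixture(scope="session")
def chain_network():
    """Six-node Ising chain with uniform couplings, balanced activation."""
    P = 6
    W = np.zeros((P, P))
    for i in range(P - 1):
        W[i, i + 1] = W[i + 1, i] = 1.2
    tau = np.full(P, -0.6)
    return IsingNetwork(tau, W, tuple(f"N{i}" for i in range(P)))


def make_survey(values: np.ndarray, **extra) -> ResponseDataset:
    """Wrap a raw n × 27 integer matrix as a ResponseDataset."""
    table = pd.DataFrame(values, columns=list(SENNC_ITEMS))
    table.insert(0, "respondent_id", np.arange(len(table)))
    for k, v in extra.items():
        table[k] = v
    return ResponseDataset(table)


def exact_covariance_data(cov: np.ndarray, n: int, seed: int = 0) -> np.ndarray:
    """Draw data whose *sample* covariance equals ``cov`` exactly.

    Whitens a random sample to identity covariance and re-colours it, so
    closed-form expressions in the population become exact in the sample.
    """
    rng = np.random.default_rng(seed)
    p = cov.shape[0]
    X = rng.standard_normal((n, p))
    X -= X.mean(axis=0)
    S = np.cov(X, rowvar=False)
    X = X @ np.linalg.inv(np.linalg.cholesky(S)).T
    return X @ np.linalg.cholesky(cov).T
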