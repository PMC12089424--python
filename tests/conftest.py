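import numpy as np
import pandas as pd
import pytest

from cogvar import irt
from cogvar.models import ModelSpec, ScoredDataset


@pytest.fixture
def binary_item():
    return irt.Item(a=1.0, b=(0.0,))


@pytest.fixture
def small_binary_bank():
    """Six binary items, symmetric thresholds around 0."""
    bs = np.linspace(-1.5, 1.5, 6)
    return irt.ItemBank(
        items=tuple(irt.Item(a=1.2, b=(float(b),)) for b in bs),
        domain_label="small",
    )


@pytest.fixture
def graded_item():
    return irt.Item(a=1.4, b=(-1.0, 0.2, 1.1))


def make_regression_data(n, beta0=2.0, beta1=1.0, sigma=1.0, sem=None, seed=0):
    """y = beta0 + beta1*x + N(0, sigma^2) [+ N(0, sem_i^2) observation noise]."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    latent = beta0 + beta1 * x + rng.normal(0.0, sigma, size=n)
    if sem is None:
        sem_vec = np.zeros(n)
        y = latent
    else:
        sem_vec = np.broadcast_to(np.asarray(sem, dtype=float), (n,)).copy()
        if sem_vec.ndim == 0:
            sem_vec = np.full(n, float(sem))
        y = latent + rng.normal(0.0, 1.0, size=n) * sem_vec
    df = pd.DataFrame({"score": y, "x": x, "sem": sem_vec, "latent": latent})
    return ScoredDataset(df)


@pytest.fixture
def simple_spec():
    return ModelSpec(outcome="score", biomarkers=("x",), phase=None)


@pytest.fixture
def simple_me_spec():
    return ModelSpec(outcome="score", biomarkers=("x",), phase=None, account_for_me=True)
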