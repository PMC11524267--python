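import numpy as np
import pytest

from hbpls.simulate import SimSpec, make_worked_fixture, simulate


@pytest.fixture(scope="session")
def worked_fixture():
    """Tiny deterministic dataset (10 x 4 X, 10 x 2 Y) for exact checks."""
    return make_worked_fixture()


@pytest.fixture(scope="session")
def planted_dataset():
    """One realization of the default planted-regulator simulation."""
    return simulate(SimSpec(seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def standardized_regression_instance(seed, n=40, p=8, noise=1.0):
    """Centered, column-standardized regression data for solver tests."""
    r = np.random.default_rng(seed)
    X = r.standard_normal((n, p))
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    beta = r.standard_normal(p)
    y = X @ beta + noise * r.standard_normal(n)
    y = y - y.mean()
    return X, y, beta
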