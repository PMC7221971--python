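import numpy as np
import pytest

from graphppi import synthetic
from graphppi.features import SubstitutionMatrix, default_contact_matrix


@pytest.fixture(scope="session")
def unit_matrix():
    return SubstitutionMatrix.unit()


@pytest.fixture(scope="session")
def contact_matrix():
    return default_contact_matrix()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """A quick synthetic dataset with a strong planted signal."""
    spec = synthetic.SyntheticSpec(
        n_pos=30, n_neg=30, length_range=(50, 90), delta=0.8, seed=7
    )
    return synthetic.generate_dataset(spec)


def bpdn_oracle(X, y, w, eps):
    """Independent convex-programming solution of the weighted L1 problem.

    Split-variable reformulation (beta = u - v, u, v >= 0) with the smooth
    quadratic constraint eps^2 - ||y - X beta||^2 >= 0, solved by SLSQP.
    """
    from scipy.optimize import minimize

    m, n = X.shape
    c = np.concatenate([w, w])

    def con(z):
        r = y - X @ (z[:n] - z[n:])
        return eps**2 - float(r @ r)

    def con_jac(z):
        r = y - X @ (z[:n] - z[n:])
        g = 2 * X.T @ r
        return np.concatenate([g, -g])

    b0, *_ = np.linalg.lstsq(X, y, rcond=None)
    z0 = np.concatenate([np.maximum(b0, 0), np.maximum(-b0, 0)])
    res = minimize(
        lambda z: float(c @ z), z0, jac=lambda z: c,
        bounds=[(0, None)] * (2 * n),
        constraints=[{"type": "ineq", "fun": con, "jac": con_jac}],
        method="SLSQP", options={"maxiter": 2000, "ftol": 1e-14},
    )
    beta = res.x[:n] - res.x[n:]
    return beta, float(np.abs(w * beta).sum())


def random_bpdn_instance(rng, m_max=6, n_max=10):
    """A random feasible weighted-BPDN instance (wide dictionary)."""
    m = int(rng.integers(3, m_max + 1))
    n = int(rng.integers(m + 1, n_max + 1))
    X = rng.normal(size=(m, n))
    X /= np.linalg.norm(X, axis=0)
    y = rng.normal(size=m)
    y /= np.linalg.norm(y)
    w = rng.uniform(0.5, 2.0, n)
    eps = float(rng.uniform(0.05, 0.3))
    return X, y, w, eps
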