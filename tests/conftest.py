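import numpy as np
import pytest

from isoprobit import (
    DoseResponseDataset,
    DrugTruth,
    FixedRatioDesign,
    inverse_probit,
    load_fixture_graph,
)
from isoprobit.io import load_published_summary


@pytest.fixture(scope="session")
def fixture_graph():
    return load_fixture_graph()


@pytest.fixture(scope="session")
def summary():
    return load_published_summary()


@pytest.fixture
def ex527_like_truth():
    """A SIRT1-inhibitor-like drug: IC50 50 µM, probit slope 2.3."""
    return DrugTruth("A", true_ic50=50.0, true_slope=2.3)


@pytest.fixture
def pax_like_truth():
    """A sub-micromolar partner drug with the same slope."""
    return DrugTruth("B", true_ic50=0.8, true_slope=2.3)


@pytest.fixture
def design():
    return FixedRatioDesign(0.5, "A", "B")


def probit_noise_dataset(
    label, slope, intercept, rng, doses=None, replicates=8, noise_sd=0.25
):
    """Probit-linear data with homoscedastic Gaussian noise on the probit
    scale — the regime where OLS standard-error formulas are exact."""
    if doses is None:
        doses = 50.0 * np.array([0.25, 0.5, 1.0, 2.0, 4.0, 8.0])
    doses = np.repeat(np.asarray(doses, dtype=float), replicates)
    y = slope * np.log10(doses) + intercept + rng.normal(0.0, noise_sd, doses.size)
    return DoseResponseDataset.from_arrays(label, doses, inverse_probit(y))


def ols_normal_equations(x, y):
    """Independent OLS oracle: explicit normal equations.

    Returns (intercept, slope, se_intercept, se_slope, cov_ab, r_squared).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    X = np.column_stack([np.ones(n), x])
    xtx = X.T @ X
    beta = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    if n > 2:
        s2 = rss / (n - 2)
        cov = s2 * np.linalg.inv(xtx)
        se_a, se_b = np.sqrt(cov[0, 0]), np.sqrt(cov[1, 1])
        cov_ab = cov[0, 1]
    else:
        se_a = se_b = cov_ab = 0.0
    return beta[0], beta[1], se_a, se_b, cov_ab, r2
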