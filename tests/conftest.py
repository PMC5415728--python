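import numpy as np
import pytest
from scipy import stats as sps

from nbpower import DispersionTrend

# Default bulk RNA-Seq-style mean-dispersion trend used across the tests.
TREND = DispersionTrend(a0=0.26, a1=3.65)


@pytest.fixture
def trend():
    return TREND


@pytest.fixture
def rng():
    return np.random.default_rng(20230917)


def grid_oracle_loglik(x, y, mu1, mu2, shared_phi=True, grid_size=10_000,
                       lo=1e-6, hi=50.0):
    """Brute-force profile-likelihood oracle, independent of the package.

    Maximizes the NB log-likelihood over a log-spaced dispersion grid with
    the group means fixed at the given values, using scipy's nbinom pmf
    (size = 1/phi, p = size/(size+mu)).  Returns the attained maximum.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    phis = np.exp(np.linspace(np.log(lo), np.log(hi), grid_size))
    r = 1.0 / phis
    llx = sps.nbinom.logpmf(x[:, None], r, r / (r + mu1)).sum(axis=0)
    lly = sps.nbinom.logpmf(y[:, None], r, r / (r + mu2)).sum(axis=0)
    if shared_phi:
        return float((llx + lly).max())
    return float(llx.max() + lly.max())
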