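"""Negative binomial primitives in the mean-dispersion parameterization.

A count :math:`X \\sim \\mathrm{NB}(\\mu, \\phi)` has mean ``mu`` and variance
``mu + mu**2 * phi``; ``phi -> 0`` recovers the Poisson distribution.  The
module also provides the mean-dispersion functional trend
``phi_tr(mu) = a1 / mu + a0`` used to tie a gene's expected dispersion to its
mean expression, and seeded, reproducible count simulation via the
gamma-Poisson mixture.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

__all__ = [
    "NBParams",
    "DispersionTrend",
    "nb_log_pmf",
    "dispersion_at",
    "simulate_counts",
    "substream",
    "stable_key",
]


@dataclass(frozen=True)
class NBParams:
    """Parameters of one negative binomial distribution.

    Attributes
    ----------
    mu : float
        Mean expression count, strictly positive.
    phi : float
        Dispersion (dimensionless), strictly positive.  The implied
        variance is ``mu + mu**2 * phi``.
    """

    mu: float
    phi: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.mu) and self.mu > 0):
            raise ValueError(f"mu must be a positive finite real, got {self.mu!r}")
        if not (np.isfinite(self.phi) and self.phi > 0):
            raise ValueError(f"phi must be a positive finite real, got {self.phi!r}")

    @property
    def variance(self) -> float:
        return self.mu + self.mu**2 * self.phi


@dataclass(frozen=True)
class DispersionTrend:
    """Mean-dispersion functional trend ``phi_tr(mu) = a1 / mu + a0``.

    ``a0`` is the asymptotic dispersion at large mean expression; ``a1``
    governs how strongly dispersion inflates at low counts.  Both must be
    non-negative and not both zero, so the trend is strictly positive for
    every ``mu > 0``.
    """

    a0: float
    a1: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.a0) and self.a0 >= 0):
            raise ValueError(f"a0 must be a non-negative finite real, got {self.a0!r}")
        if not (np.isfinite(self.a1) and self.a1 >= 0):
            raise ValueError(f"a1 must be a non-negative finite real, got {self.a1!r}")
        if self.a0 == 0 and self.a1 == 0:
            raise ValueError("a0 and a1 cannot both be zero")


def dispersion_at(trend: DispersionTrend, mu):
    """Evaluate the dispersion trend at mean expression ``mu``.

    Accepts a scalar or array of strictly positive means and returns
    ``a1 / mu + a0`` elementwise.
    """
    mu = np.asarray(mu, dtype=float)
    if not np.all(np.isfinite(mu) & (mu > 0)):
        raise ValueError("mu must be strictly positive and finite")
    out = trend.a1 / mu + trend.a0
    return float(out) if out.ndim == 0 else out


def nb_log_pmf(x, params: NBParams):
    """Log probability mass of NB(mu, phi) at non-negative integer(s) ``x``.

    Evaluated entirely through log-gamma functions so that it stays finite
    for counts in the thousands, where the raw gamma ratios overflow.
    """
    x = np.asarray(x)
    if not np.issubdtype(x.dtype, np.number):
        raise ValueError("x must be numeric")
    if np.any(x < 0) or np.any(np.asarray(x, dtype=float) != np.floor(x)):
        raise ValueError("x must consist of non-negative integers")
    x = np.asarray(x, dtype=float)
    mu, phi = params.mu, params.phi
    r = 1.0 / phi
    # log[(1/(1+mu*phi))^(1/phi)] = -log1p(mu*phi)/phi; the x-dependent factor
    # is x*log(mu*phi/(1+mu*phi)).
    out = (
        gammaln(x + r)
        - gammaln(r)
        - gammaln(x + 1.0)
        - np.log1p(mu * phi) / phi
        + x * (np.log(mu * phi) - np.log1p(mu * phi))
    )
    return float(out) if out.ndim == 0 else out


def substream(seed: int, *key: int) -> np.random.Generator:
    """Independent generator for the sub-task identified by ``key``.

    A single root seed expands into statistically independent substreams via
    :class:`numpy.random.SeedSequence` spawn keys, so any parallel or
    re-ordered execution of simulation batches reproduces bit-identical
    draws per task.
    """
    seed = int(seed)
    if seed < 0:
        raise ValueError("seed must be a non-negative integer")
    ss = np.random.SeedSequence(seed, spawn_key=tuple(int(k) for k in key))
    return np.random.Generator(np.random.PCG64(ss))


def stable_key(*parts) -> int:
    """Deterministic 31-bit integer derived from a tuple of hashables.

    Used to key seed substreams on design parameters so that caching and
    parallel execution cannot change which draws a given scenario sees.
    """
    text = "|".join(repr(p) for p in parts)
    return zlib.crc32(text.encode("utf-8")) & 0x7FFFFFFF


def _gamma_poisson(rng: np.random.Generator, mu, phi, size):
    """Draws from NB(mu, phi) as a Poisson with gamma-distributed rate.

    The rate is gamma(shape=1/phi, scale=mu*phi), which marginalizes to a
    negative binomial with size parameter 1/phi — the single place the
    size = 1/phi convention is fixed.
    """
    lam = rng.gamma(shape=1.0 / phi, scale=mu * phi, size=size)
    return rng.poisson(lam)


def simulate_counts(params: NBParams, n: int, seed) -> np.ndarray:
    """Simulate ``n`` iid counts from NB(mu, phi).

    ``seed`` may be an integer (expanded via :func:`substream`) or an
    existing :class:`numpy.random.Generator`.  Identical seeds give
    identical output.
    """
    n = int(n)
    if n < 1:
        raise ValueError("n must be a positive integer")
    rng = seed if isinstance(seed, np.random.Generator) else substream(seed)
    return _gamma_poisson(rng, params.mu, params.phi, n)
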