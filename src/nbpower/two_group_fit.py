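"""Two-group negative binomial fits and the Wald / likelihood-ratio tests.

The model: counts ``x_1..x_{n1}`` from condition 1 are NB(mu, phi1) and
``y_1..y_{n2}`` from condition 2 are NB(gamma*mu, phi2), with gamma the
fold ratio under test (H0: gamma = 1).  The mean MLEs have closed forms —
under the null the pooled mean ``(n1*xbar + n2*ybar)/(n1+n2)``, under the
alternative ``mu_hat = xbar`` and ``gamma_hat = ybar/xbar`` — so only the
dispersion(s) require numerical optimization, done by a bounded
golden-section search on log(phi).  Everything is vectorized across
replicate datasets: the same search runs simultaneously for an arbitrary
batch, which is what makes Monte-Carlo calibration with 1e5 replicates
practical.

The Wald statistic is ``(log(gamma_hat) / se_log_gamma)**2``, where
``se_log_gamma`` comes from the numerically differentiated observed
information of the full log-parameterization (log mu, log gamma, log phi,
or per-group log phis in the unequal-dispersion model).

Datasets where either group's sample mean is zero leave the fold ratio
non-estimable (gamma_hat in {0, inf}); these return NaN sentinels, and the
calibration / power layers exclude them while reporting the exclusion
fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import SimpleNamespace

import numpy as np
from scipy.special import gammaln

__all__ = [
    "TwoGroupData",
    "DispersionMode",
    "FitResult",
    "fit_null",
    "fit_alt",
    "lrt_statistic",
    "wald_statistic",
    "batch_statistics",
    "PHI_LOWER",
    "PHI_UPPER",
]

PHI_LOWER = 1e-6
PHI_UPPER = 50.0
_GOLDEN_ITERS = 60
_LRT_CLIP = 1e-8
_HESS_STEP = 1e-5


@dataclass(frozen=True)
class TwoGroupData:
    """Counts for one gene under two conditions (n1, n2 >= 2)."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x)
        y = np.asarray(self.y)
        for name, arr in (("x", x), ("y", y)):
            if arr.ndim != 1 or arr.size < 2:
                raise ValueError(f"{name} must be a 1-d vector with at least 2 entries")
            if np.any(arr < 0) or np.any(np.asarray(arr, float) != np.floor(arr)):
                raise ValueError(f"{name} must contain non-negative integers")
        object.__setattr__(self, "x", np.asarray(x, dtype=np.int64))
        object.__setattr__(self, "y", np.asarray(y, dtype=np.int64))


@dataclass(frozen=True)
class DispersionMode:
    """Dispersion structure across the two conditions.

    ``mode='equal'`` fits one shared dispersion; ``mode='unequal'`` fits a
    free dispersion per group.  ``ratio`` is the simulation-side ratio
    phi2/phi1 used by the power engine when generating unequal-dispersion
    data; it plays no role in fitting and is ignored when mode is equal.
    """

    mode: str = "equal"
    ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("equal", "unequal"):
            raise ValueError(f"mode must be 'equal' or 'unequal', got {self.mode!r}")
        if not (np.isfinite(self.ratio) and self.ratio > 0):
            raise ValueError(f"ratio must be a positive real, got {self.ratio!r}")


@dataclass(frozen=True)
class FitResult:
    """MLEs and log-likelihood for one two-group dataset.

    ``phi_hat`` is a single float in equal mode and a (phi1, phi2) tuple in
    unequal mode.  ``gamma_hat`` is NaN when non-estimable (a group mean of
    zero).  ``se_log_gamma`` is populated only by the alternative fit.
    """

    mu_hat: float
    gamma_hat: float
    phi_hat: object
    loglik: float
    se_log_gamma: float | None
    converged: bool


# ---------------------------------------------------------------------------
# vectorized profile likelihood


def _group_loglik(counts: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB log-likelihood of each row of ``counts`` at its own (mu, phi).

    counts: (T, n); mu, phi: (T,).  Requires mu > 0 for every row.
    """
    n = counts.shape[1]
    r = 1.0 / phi
    mp = mu * phi
    ll = gammaln(counts + r[:, None]).sum(axis=1)
    ll -= n * gammaln(r)
    ll -= gammaln(counts + 1.0).sum(axis=1)
    ll += counts.sum(axis=1) * (np.log(mp) - np.log1p(mp))
    ll -= n * np.log1p(mp) / phi
    return ll


def _profile_phi(groups, iters: int = _GOLDEN_ITERS):
    """Maximize the summed log-likelihood of ``groups`` over a shared phi.

    ``groups`` is a sequence of (counts (T,n), mu (T,)) pairs that share the
    dispersion.  Golden-section search on z = log(phi) over
    [log(PHI_LOWER), log(PHI_UPPER)], run elementwise across the T rows.
    Returns (phi (T,), loglik (T,), at_bound (T,) bool).
    """
    T = groups[0][0].shape[0]

    def f(z):
        phi = np.exp(z)
        total = np.zeros(T)
        for counts, mu in groups:
            total += _group_loglik(counts, mu, phi)
        return total

    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a = np.full(T, np.log(PHI_LOWER))
    b = np.full(T, np.log(PHI_UPPER))
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(iters):
        left = fc >= fd  # maximum in [a, d]
        b = np.where(left, d, b)
        a = np.where(left, a, c)
        znew = np.where(left, b - invphi * (b - a), a + invphi * (b - a))
        fnew = f(znew)
        c, d, fc, fd = (
            np.where(left, znew, d),
            np.where(left, c, znew),
            np.where(left, fnew, fd),
            np.where(left, fc, fnew),
        )
    z = 0.5 * (a + b)
    loglik = f(z)
    at_bound = (z - np.log(PHI_LOWER) < 1e-3) | (np.log(PHI_UPPER) - z < 1e-3)
    return np.exp(z), loglik, at_bound


def _full_loglik(x, y, theta, unequal: bool) -> np.ndarray:
    """Log-likelihood at the full log-parameterization, per row.

    theta columns: (log mu, log gamma, log phi) or
    (log mu, log gamma, log phi1, log phi2).
    """
    mu1 = np.exp(theta[:, 0])
    mu2 = np.exp(theta[:, 0] + theta[:, 1])
    if unequal:
        phi1, phi2 = np.exp(theta[:, 2]), np.exp(theta[:, 3])
    else:
        phi1 = phi2 = np.exp(theta[:, 2])
    return _group_loglik(x, mu1, phi1) + _group_loglik(y, mu2, phi2)


def _se_log_gamma(x, y, theta, unequal: bool, step: float = _HESS_STEP):
    """Standard error of log(gamma_hat) from the observed information.

    Central-difference Hessian of the log-likelihood on the log-parameter
    scale at the MLE, negated, inverted per row; the square root of the
    log-gamma diagonal entry of the inverse.  Rows with a singular or
    non-positive-definite information return NaN.
    """
    T, p = theta.shape
    H = np.empty((T, p, p))
    f0 = _full_loglik(x, y, theta, unequal)
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = step
        fp = _full_loglik(x, y, theta + ei, unequal)
        fm = _full_loglik(x, y, theta - ei, unequal)
        H[:, i, i] = (fp - 2.0 * f0 + fm) / step**2
        for j in range(i + 1, p):
            ej = np.zeros(p)
            ej[j] = step
            fpp = _full_loglik(x, y, theta + ei + ej, unequal)
            fpm = _full_loglik(x, y, theta + ei - ej, unequal)
            fmp = _full_loglik(x, y, theta - ei + ej, unequal)
            fmm = _full_loglik(x, y, theta - ei - ej, unequal)
            H[:, i, j] = H[:, j, i] = (fpp - fpm - fmp + fmm) / (4.0 * step**2)
    info = -H
    det = np.linalg.det(info)
    bad = ~np.isfinite(det) | (np.abs(det) < 1e-300)
    info[bad] = np.eye(p)
    inv = np.linalg.inv(info)
    var = inv[:, 1, 1]
    bad |= ~np.isfinite(var) | (var <= 0)
    se = np.sqrt(np.where(bad, np.nan, var))
    return se


# ---------------------------------------------------------------------------
# batch interface (consumed by calibration and power_engine)


def batch_fit(x: np.ndarray, y: np.ndarray, mode: DispersionMode,
              need_wald: bool = True, need_lrt: bool = True) -> SimpleNamespace:
    """Fit the null and alternative models for a batch of datasets.

    x: (T, n1), y: (T, n2) integer count matrices, one replicate per row.
    Returns a namespace with per-row arrays: ``lrt``, ``wald``,
    ``gamma_hat``, ``estimable`` (bool mask; NaN statistics elsewhere).
    """
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    T = x.shape[0]
    n1, n2 = x.shape[1], y.shape[1]
    xbar = x.mean(axis=1)
    ybar = y.mean(axis=1)
    estimable = (xbar > 0) & (ybar > 0)
    unequal = mode.mode == "unequal"

    lrt = np.full(T, np.nan)
    wald = np.full(T, np.nan)
    gamma_hat = np.full(T, np.nan)
    gamma_hat[estimable] = ybar[estimable] / xbar[estimable]

    if not np.any(estimable):
        return SimpleNamespace(lrt=lrt, wald=wald, gamma_hat=gamma_hat,
                               estimable=estimable)

    xs, ys = x[estimable], y[estimable]
    xb, yb = xbar[estimable], ybar[estimable]
    pooled = (n1 * xb + n2 * yb) / (n1 + n2)

    if need_lrt:
        if unequal:
            _, ll0x, _ = _profile_phi([(xs, pooled)])
            _, ll0y, _ = _profile_phi([(ys, pooled)])
            ll0 = ll0x + ll0y
        else:
            _, ll0, _ = _profile_phi([(xs, pooled), (ys, pooled)])

    if unequal:
        phi1, ll1x, _ = _profile_phi([(xs, xb)])
        phi2, ll1y, _ = _profile_phi([(ys, yb)])
        ll1 = ll1x + ll1y
        theta = np.column_stack([np.log(xb), np.log(yb / xb),
                                 np.log(phi1), np.log(phi2)])
    else:
        phi, ll1, _ = _profile_phi([(xs, xb), (ys, yb)])
        theta = np.column_stack([np.log(xb), np.log(yb / xb), np.log(phi)])

    if need_lrt:
        stat = -2.0 * (ll0 - ll1)
        stat = np.where((stat < 0) & (stat > -_LRT_CLIP), 0.0, stat)
        stat = np.where(stat < 0, np.nan, stat)  # beyond tolerance: flagged
        lrt[estimable] = stat

    if need_wald:
        se = _se_log_gamma(xs, ys, theta, unequal)
        wald[estimable] = (np.log(yb / xb) / se) ** 2

    return SimpleNamespace(lrt=lrt, wald=wald, gamma_hat=gamma_hat,
                           estimable=estimable)


def batch_statistics(x: np.ndarray, y: np.ndarray, mode: DispersionMode,
                     statistic: str) -> tuple[np.ndarray, int]:
    """Chosen test statistic for each row of a batch of datasets.

    Returns (retained statistics, number excluded).  Excluded rows are
    those with a zero group mean (fold ratio non-estimable) or an invalid
    standard error / negative likelihood ratio beyond tolerance.
    """
    if statistic not in ("wald", "lrt"):
        raise ValueError(f"statistic must be 'wald' or 'lrt', got {statistic!r}")
    fit = batch_fit(x, y, mode,
                    need_wald=statistic == "wald",
                    need_lrt=statistic == "lrt")
    stats = fit.wald if statistic == "wald" else fit.lrt
    keep = np.isfinite(stats)
    return stats[keep], int(stats.size - keep.sum())


# ---------------------------------------------------------------------------
# single-dataset interface


def _phi_scalar(phi_arr, unequal: bool, second=None):
    if unequal:
        return (float(phi_arr[0]), float(second[0]))
    return float(phi_arr[0])


def fit_null(data: TwoGroupData, mode: DispersionMode) -> FitResult:
    """Constrained MLE under H0: gamma = 1.

    Both groups share the pooled mean ``(n1*xbar + n2*ybar)/(n1+n2)``; the
    dispersion(s) maximize the constrained likelihood by bounded search.
    """
    x, y = data.x, data.y
    if x.sum() + y.sum() == 0:
        raise ValueError("all counts are zero: the null model is undefined")
    n1, n2 = x.size, y.size
    pooled = np.array([(n1 * x.mean() + n2 * y.mean()) / (n1 + n2)])
    xs, ys = x[None, :], y[None, :]
    if mode.mode == "unequal":
        p1, llx, bx = _profile_phi([(xs, pooled)])
        p2, lly, by = _profile_phi([(ys, pooled)])
        phi_hat = (float(p1[0]), float(p2[0]))
        loglik = float(llx[0] + lly[0])
        converged = not (bx[0] or by[0])
    else:
        p, ll, bound = _profile_phi([(xs, pooled), (ys, pooled)])
        phi_hat = float(p[0])
        loglik = float(ll[0])
        converged = not bound[0]
    return FitResult(mu_hat=float(pooled[0]), gamma_hat=1.0, phi_hat=phi_hat,
                     loglik=loglik, se_log_gamma=None, converged=converged)


def fit_alt(data: TwoGroupData, mode: DispersionMode) -> FitResult:
    """Unconstrained MLE: mu_hat = xbar, gamma_hat = ybar/xbar.

    Returns the NaN sentinel for gamma_hat (and statistics downstream) when
    either group's sample mean is zero, since gamma_hat would be 0 or
    infinite and the tests undefined.
    """
    x, y = data.x, data.y
    xbar, ybar = float(x.mean()), float(y.mean())
    if xbar == 0 or ybar == 0:
        return FitResult(mu_hat=xbar, gamma_hat=np.nan, phi_hat=np.nan,
                         loglik=np.nan, se_log_gamma=None, converged=False)
    xs, ys = x[None, :], y[None, :]
    mux = np.array([xbar])
    muy = np.array([ybar])
    unequal = mode.mode == "unequal"
    if unequal:
        p1, llx, bx = _profile_phi([(xs, mux)])
        p2, lly, by = _profile_phi([(ys, muy)])
        phi_hat = (float(p1[0]), float(p2[0]))
        loglik = float(llx[0] + lly[0])
        converged = not (bx[0] or by[0])
        theta = np.array([[np.log(xbar), np.log(ybar / xbar),
                           np.log(p1[0]), np.log(p2[0])]])
    else:
        p, ll, bound = _profile_phi([(xs, mux), (ys, muy)])
        phi_hat = float(p[0])
        loglik = float(ll[0])
        converged = not bound[0]
        theta = np.array([[np.log(xbar), np.log(ybar / xbar), np.log(p[0])]])
    se = float(_se_log_gamma(xs, ys, theta, unequal)[0])
    return FitResult(mu_hat=xbar, gamma_hat=ybar / xbar, phi_hat=phi_hat,
                     loglik=loglik, se_log_gamma=se if np.isfinite(se) else None,
                     converged=converged)


def lrt_statistic(data: TwoGroupData, mode: DispersionMode) -> float:
    """Likelihood-ratio statistic -2*(loglik_null - loglik_alt) for H0: gamma=1.

    Non-negative by model nesting; values in (-1e-8, 0) from optimizer
    tolerance are clipped to zero.  NaN when the fold ratio is
    non-estimable.
    """
    alt = fit_alt(data, mode)
    if not np.isfinite(alt.gamma_hat):
        return np.nan
    null = fit_null(data, mode)
    stat = -2.0 * (null.loglik - alt.loglik)
    if -_LRT_CLIP < stat < 0:
        stat = 0.0
    return stat


def wald_statistic(data: TwoGroupData, mode: DispersionMode) -> float:
    """Wald statistic (log(gamma_hat) / se_log_gamma)**2 for H0: log(gamma)=0.

    NaN when gamma_hat is non-estimable or the observed information is
    singular.
    """
    alt = fit_alt(data, mode)
    if not np.isfinite(alt.gamma_hat) or alt.se_log_gamma is None:
        return np.nan
    return float((np.log(alt.gamma_hat) / alt.se_log_gamma) ** 2)
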