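"""Simulation-based power estimation and sample-size search.

For a design (per-group sample sizes, control mean mu, fold ratio gamma,
nominal level alpha, dispersion structure from the mean-dispersion trend),
power is estimated by the procedure: derive the dispersion from the trend,
simulate T_null null datasets to obtain the empirical 100*(1-alpha)th
percentile cutoff, simulate T_alt datasets under the alternative
(condition-2 mean gamma*mu), and report the fraction of alternative
statistics exceeding the cutoff.  An independent null batch scores the
achieved false positive rate at the same cutoff, so every power estimate
carries its own error-control check.

Null calibrations are the dominant cost and do not depend on gamma or
alpha, so grid sweeps cache and reuse them across those axes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import (
    STREAM_ALT,
    STREAM_EVAL,
    STREAM_NULL,
    DesignSpec,
    empirical_critical_value,
    estimate_fpr,
    simulate_null_statistics,
)
from .nb_core import stable_key
from .two_group_fit import batch_statistics

__all__ = [
    "PowerResult",
    "SampleSizeResult",
    "estimate_power",
    "power_grid",
    "sample_size_for_power",
    "results_table",
]


@dataclass(frozen=True)
class PowerResult:
    """Estimated power for one design, with its Monte-Carlo provenance."""

    design: DesignSpec
    critical_value: float
    power: float
    power_mc_se: float
    exclusion_fraction_alt: float
    exclusion_fraction_null: float
    fpr_achieved: float


@dataclass(frozen=True)
class SampleSizeResult:
    """Outcome of the per-group sample-size search.

    ``n`` is the smallest per-group size reaching the target power, or None
    when even ``n_max`` falls short (``achieved`` False).  ``curve`` holds
    the (n, power) pairs actually evaluated during the search.
    """

    n: int | None
    achieved: bool
    target_power: float
    curve: pd.DataFrame


def _alt_statistics(design: DesignSpec, stream_key):
    from .calibration import _simulate_batch

    x, y = _simulate_batch(design, design.T_alt, design.gamma, stream_key)
    return batch_statistics(x, y, design.dispersion_mode, design.statistic)


def estimate_power(design: DesignSpec, _null_cache=None,
                   stream_prefix: tuple | None = None) -> PowerResult:
    """Estimate power and the achieved false positive rate for one design.

    ``_null_cache`` optionally supplies precomputed
    (null statistics, exclusion fraction, evaluation-batch statistics) for
    this design's null, letting grid sweeps reuse calibrations; results
    are identical either way because every batch draws from a substream
    keyed on the design — never on execution order — so a degenerate grid,
    a cached sweep and a direct call all agree exactly.
    """
    if stream_prefix is None:
        stream_prefix = (stable_key(*_null_key(design)),)
    if _null_cache is None:
        null_stats, excl_null = simulate_null_statistics(
            design, stream_key=stream_prefix + (STREAM_NULL,))
        eval_stats, _ = simulate_null_statistics(
            design, stream_key=stream_prefix + (STREAM_EVAL,))
    else:
        null_stats, excl_null, eval_stats = _null_cache

    cutoff = empirical_critical_value(null_stats, design.alpha)
    alt_key = stream_prefix + (STREAM_ALT, stable_key(design.gamma))
    alt_stats, n_excl_alt = _alt_statistics(design, alt_key)
    power = estimate_fpr(alt_stats, cutoff)  # same tail functional
    t_ret = alt_stats.size
    return PowerResult(
        design=design,
        critical_value=cutoff,
        power=power,
        power_mc_se=float(np.sqrt(power * (1.0 - power) / t_ret)),
        exclusion_fraction_alt=n_excl_alt / design.T_alt,
        exclusion_fraction_null=excl_null,
        fpr_achieved=estimate_fpr(eval_stats, cutoff),
    )


def _null_key(design: DesignSpec) -> tuple:
    """Cache / substream key for a design's null: everything but gamma, alpha."""
    mode = design.dispersion_mode
    return (design.statistic, mode.mode,
            mode.ratio if mode.mode == "unequal" else 1.0,
            design.n1, design.n2, design.mu,
            design.trend.a0, design.trend.a1,
            design.T_null, design.seed)


def power_grid(base: DesignSpec, n_values, mu_values, gamma_values,
               alpha_values, n_jobs: int = 1) -> pd.DataFrame:
    """Power over the cross product of the four grids.

    Each cell is ``estimate_power`` on ``base`` with (n1=n2=n, mu, gamma,
    alpha) substituted.  Null calibrations are shared across gamma and
    alpha within each (n, mu) cell.  With ``n_jobs > 1`` cells run in
    parallel via joblib; per-cell substreams make the output independent
    of scheduling.
    """
    n_values = list(n_values)
    mu_values = list(mu_values)
    gamma_values = list(gamma_values)
    alpha_values = list(alpha_values)
    if not (n_values and mu_values and gamma_values and alpha_values):
        raise ValueError("all grids must be non-empty")

    cells = [(n, mu, g, a)
             for n in n_values for mu in mu_values
             for g in gamma_values for a in alpha_values]

    null_cache: dict[tuple, tuple] = {}

    def _null_for(design: DesignSpec):
        key = _null_key(design)
        if key not in null_cache:
            prefix = (stable_key(*key),)
            null_stats, excl = simulate_null_statistics(
                design, stream_key=prefix + (STREAM_NULL,))
            eval_stats, _ = simulate_null_statistics(
                design, stream_key=prefix + (STREAM_EVAL,))
            null_cache[key] = (null_stats, excl, eval_stats)
        return null_cache[key]

    def _run(cell):
        n, mu, g, a = cell
        design = base.with_(n1=int(n), n2=int(n), mu=float(mu),
                            gamma=float(g), alpha=float(a))
        prefix = (stable_key(*_null_key(design)),)
        return estimate_power(design, _null_cache=_null_for(design),
                              stream_prefix=prefix)

    if n_jobs > 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=n_jobs)(delayed(_run)(c) for c in cells)
    else:
        results = [_run(c) for c in cells]
    return results_table(results)


def results_table(results) -> pd.DataFrame:
    """Flatten PowerResults into the standard TSV-ready table."""
    rows = []
    for r in results:
        d = r.design
        rows.append({
            "statistic": d.statistic,
            "mode": d.dispersion_mode.mode,
            "n1": d.n1, "n2": d.n2,
            "mu": d.mu, "gamma": d.gamma, "alpha": d.alpha,
            "critical_value": r.critical_value,
            "power": r.power,
            "mc_se": r.power_mc_se,
            "fpr_achieved": r.fpr_achieved,
            "exclusion_fraction": r.exclusion_fraction_alt,
            "seed": d.seed,
        })
    return pd.DataFrame(rows)


def sample_size_for_power(base: DesignSpec, target_power: float,
                          n_min: int = 2, n_max: int = 100) -> SampleSizeResult:
    """Smallest per-group n in [n_min, n_max] with estimated power >= target.

    Brackets by doubling from ``n_min``, then bisects on the integer grid.
    Because Monte-Carlo power is not strictly monotone, decisions use the
    running maximum of the power evaluated at or below each n; the search
    then walks downward from the bracketing solution while the target
    stays met.  Returns ``achieved=False`` when even ``n_max`` falls short.
    """
    if not (0 < target_power < 1):
        raise ValueError("target_power must lie in (0, 1)")
    if n_min < 2:
        raise ValueError("n_min must be at least 2")
    if n_max < n_min:
        raise ValueError("n_max must be >= n_min")

    cache: dict[int, float] = {}

    def power_at(n: int) -> float:
        if n not in cache:
            cache[n] = estimate_power(base.with_(n1=n, n2=n)).power
        return cache[n]

    def smoothed(n: int) -> float:
        # running maximum over evaluated sizes <= n damps MC wiggle
        return max([p for m, p in cache.items() if m <= n] + [power_at(n)])

    def _result(n):
        curve = pd.DataFrame(sorted(cache.items()), columns=["n", "power"])
        return SampleSizeResult(n=n, achieved=n is not None,
                                target_power=target_power, curve=curve)

    if smoothed(n_min) >= target_power:
        return _result(n_min)

    lo, hi = n_min, None
    n = n_min
    while hi is None:
        n = min(2 * n, n_max)
        if smoothed(n) >= target_power:
            hi = n
        elif n == n_max:
            return _result(None)
        else:
            lo = n

    while hi - lo > 1:
        mid = (lo + hi) // 2
        if smoothed(mid) >= target_power:
            hi = mid
        else:
            lo = mid

    while hi > n_min and power_at(hi - 1) >= target_power:
        hi -= 1
    return _result(hi)
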