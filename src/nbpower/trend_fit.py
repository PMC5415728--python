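"""Estimate the mean-dispersion trend from a pilot count matrix.

Power calculations need the functional trend ``phi_tr(mu) = a1/mu + a0``
linking a gene's dispersion to its mean expression.  Given a pilot
genes-by-samples count matrix with a two-group annotation, this module
normalizes the counts by median-of-ratios size factors, estimates a
per-gene NB dispersion by profile maximum likelihood (free group means),
and regresses the gene-wise dispersions on the reciprocal normalized mean
with one robust trimming pass.  A synthetic pilot-matrix generator with a
known trend supports testing and examples without external data.

This is a deliberately plain trend estimator: no empirical-Bayes
shrinkage of the per-gene dispersions is applied, since only the fitted
trend — not the per-gene values — feeds the power simulations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nb_core import DispersionTrend, dispersion_at, substream
from .two_group_fit import _profile_phi

__all__ = [
    "PilotMatrix",
    "TrendFitReport",
    "normalize_counts",
    "genewise_dispersion",
    "genewise_dispersions",
    "fit_trend",
    "simulate_pilot_matrix",
    "read_counts_tsv",
    "read_labels_tsv",
]

GENEWISE_PHI_FLOOR = 1e-8
_MIN_GENES = 50
_WARN_GENES = 200


@dataclass(frozen=True)
class PilotMatrix:
    """Pilot RNA-Seq count matrix: genes x samples with two-group labels."""

    counts: np.ndarray
    group_labels: np.ndarray
    gene_ids: list

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        labels = np.asarray(self.group_labels)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-d genes x samples matrix")
        if np.any(counts < 0) or np.any(np.asarray(counts, float) != np.floor(counts)):
            raise ValueError("counts must be non-negative integers")
        if labels.shape != (counts.shape[1],):
            raise ValueError("group_labels must have one entry per sample")
        if not set(np.unique(labels)) <= {1, 2}:
            raise ValueError("group labels must be 1 or 2")
        for g in (1, 2):
            if np.sum(labels == g) < 2:
                raise ValueError(f"group {g} needs at least 2 samples")
        if len(self.gene_ids) != counts.shape[0]:
            raise ValueError("gene_ids must have one entry per gene")
        object.__setattr__(self, "counts", np.asarray(counts, dtype=np.int64))
        object.__setattr__(self, "group_labels", np.asarray(labels, dtype=np.int64))


@dataclass(frozen=True)
class TrendFitReport:
    """Fitted trend with per-gene inputs and fit diagnostics."""

    trend: DispersionTrend
    genes_used: int
    genewise: pd.DataFrame  # columns: gene_id, mean, dispersion, used
    residual_summary: dict


def normalize_counts(pilot: PilotMatrix):
    """Median-of-ratios normalization.

    Size factors are per-sample medians of count ratios to the geometric
    mean reference over genes with all-positive counts, rescaled so their
    geometric mean is 1.  Returns (normalized matrix, size factors).
    """
    counts = pilot.counts.astype(float)
    allpos = np.all(counts > 0, axis=1)
    if not np.any(allpos):
        raise ValueError("no gene has all-positive counts; cannot form the "
                         "geometric-mean reference")
    ref = np.exp(np.mean(np.log(counts[allpos]), axis=1))
    sf = np.median(counts[allpos] / ref[:, None], axis=0)
    sf = sf / np.exp(np.mean(np.log(sf)))
    return counts / sf, sf


def _group_means(rows: np.ndarray, labels: np.ndarray):
    m1 = rows[:, labels == 1].mean(axis=1)
    m2 = rows[:, labels == 2].mean(axis=1)
    return m1, m2


def genewise_dispersions(normalized: np.ndarray, group_labels: np.ndarray) -> np.ndarray:
    """Profile-ML NB dispersion for every gene (row) at once.

    Normalized counts are rounded to integers and treated as NB
    observations with free per-group means (the group sample means, the
    closed-form MLEs); the shared dispersion maximizes the profile
    likelihood by bounded search.  Genes with a zero group mean or no
    overdispersion return the floor.
    """
    labels = np.asarray(group_labels)
    rows = np.rint(np.asarray(normalized, float)).astype(np.int64)
    G = rows.shape[0]
    m1, m2 = _group_means(rows, labels)
    ok = (m1 > 0) & (m2 > 0)
    out = np.full(G, GENEWISE_PHI_FLOOR)
    if np.any(ok):
        x = rows[ok][:, labels == 1]
        y = rows[ok][:, labels == 2]
        phi, _, _ = _profile_phi([(x, m1[ok]), (y, m2[ok])])
        # rows driven to the lower search bound carry no dispersion signal
        phi = np.where(phi < 2e-6, GENEWISE_PHI_FLOOR, phi)
        out[ok] = phi
    return out


def genewise_dispersion(normalized_row: np.ndarray, group_labels) -> float:
    """Profile-ML dispersion of a single gene; floor for underdispersed rows."""
    row = np.asarray(normalized_row, float)
    if row.size < 4:
        raise ValueError("need at least 4 samples to estimate a dispersion")
    return float(genewise_dispersions(row[None, :], group_labels)[0])


def fit_trend(genewise: pd.DataFrame, min_genes: int = _MIN_GENES) -> TrendFitReport:
    """Fit dispersion = a1/mean + a0 to the gene-wise estimates.

    Uses genes with normalized mean > 1 and dispersion above the floor;
    ordinary least squares of dispersion on (1, 1/mean), then one trimming
    pass dropping residuals beyond 3 MADs and refitting.  Coefficients are
    clipped at zero.
    """
    required = {"gene_id", "mean", "dispersion"}
    if not required <= set(genewise.columns):
        raise ValueError(f"genewise table needs columns {sorted(required)}")
    means = genewise["mean"].to_numpy(dtype=float)
    disps = genewise["dispersion"].to_numpy(dtype=float)
    if np.ptp(means) == 0:
        raise ValueError("all gene means are equal: the trend is unidentifiable")
    usable = (means > 1) & (disps > 10 * GENEWISE_PHI_FLOOR)
    if usable.sum() < min_genes:
        raise ValueError(f"only {usable.sum()} usable genes "
                         f"(mean > 1, dispersion above floor); need {min_genes}")
    if usable.sum() < _WARN_GENES:
        warnings.warn(f"only {usable.sum()} usable genes; the trend fit may "
                      "be unstable below 200", UserWarning, stacklevel=2)

    def _ols(m, d):
        X = np.column_stack([np.ones_like(m), 1.0 / m])
        coef, *_ = np.linalg.lstsq(X, d, rcond=None)
        return coef, d - X @ coef

    m_u, d_u = means[usable], disps[usable]
    coef, resid = _ols(m_u, d_u)
    mad = np.median(np.abs(resid - np.median(resid)))
    if mad > 0:
        keep = np.abs(resid - np.median(resid)) <= 3 * 1.4826 * mad
    else:
        keep = np.ones_like(resid, dtype=bool)
    coef, resid = _ols(m_u[keep], d_u[keep])
    a0, a1 = max(coef[0], 0.0), max(coef[1], 0.0)

    table = genewise.copy()
    used_mask = np.zeros(len(table), dtype=bool)
    used_mask[np.flatnonzero(usable)[keep]] = True
    table["used"] = used_mask
    return TrendFitReport(
        trend=DispersionTrend(a0=a0, a1=a1),
        genes_used=int(keep.sum()),
        genewise=table,
        residual_summary={
            "rss": float(np.sum(resid**2)),
            "mad": float(mad),
            "trimmed": int(usable.sum() - keep.sum()),
        },
    )


def estimate_trend(pilot: PilotMatrix) -> TrendFitReport:
    """Full pipeline: normalize, estimate gene-wise dispersions, fit trend."""
    normalized, _ = normalize_counts(pilot)
    disps = genewise_dispersions(normalized, pilot.group_labels)
    table = pd.DataFrame({
        "gene_id": pilot.gene_ids,
        "mean": normalized.mean(axis=1),
        "dispersion": disps,
    })
    return fit_trend(table)


def simulate_pilot_matrix(G: int, S: int, trend: DispersionTrend,
                          mean_range=(4.0, 2000.0), seed: int = 0) -> PilotMatrix:
    """Synthetic pilot matrix with known mean-dispersion trend.

    Gene means are drawn log-uniformly from ``mean_range``; each gene's
    dispersion follows the trend, and counts are NB draws with equal means
    in both (balanced) groups — emulating a pilot dataset dominated by
    non-differential genes.  Deterministic given the seed.
    """
    if G < 1 or S < 4:
        raise ValueError("need G >= 1 genes and S >= 4 samples")
    lo, hi = mean_range
    if not (0 < lo <= hi):
        raise ValueError("mean_range must be positive with lo <= hi")
    rng = substream(seed, 101)
    mus = np.exp(rng.uniform(np.log(lo), np.log(hi), size=G))
    phis = dispersion_at(trend, mus)
    lam = rng.gamma(1.0 / phis[:, None], (mus * phis)[:, None], size=(G, S))
    counts = rng.poisson(lam)
    labels = np.array([1] * (S // 2) + [2] * (S - S // 2))
    gene_ids = [f"g{i:05d}" for i in range(G)]
    return PilotMatrix(counts=counts, group_labels=labels, gene_ids=gene_ids)


# ---------------------------------------------------------------------------
# plain-text I/O


def read_counts_tsv(path) -> tuple[np.ndarray, list, list]:
    """Read a genes x samples TSV (first column gene id, header of sample ids).

    Returns (counts, gene_ids, sample_ids); malformed cells raise a
    ValueError naming the offending line.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 4:
        raise ValueError("count matrix needs at least 4 sample columns")
    values = df.to_numpy()
    bad = ~np.isfinite(values.astype(float)) if values.dtype.kind == "f" else None
    arr = values.astype(float)
    invalid = (arr < 0) | (arr != np.floor(arr)) | ~np.isfinite(arr)
    if bad is not None:
        invalid |= bad
    if invalid.any():
        row = int(np.argwhere(invalid)[0][0])
        # +2: header line plus 1-based indexing
        raise ValueError(
            f"invalid count at line {row + 2} (gene {df.index[row]!r}): "
            "entries must be non-negative integers")
    return arr.astype(np.int64), list(df.index), list(df.columns)


def read_labels_tsv(path, sample_ids) -> np.ndarray:
    """Read a two-column (sample id, group) TSV and align it to sample_ids."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"],
                     dtype={"sample": str})
    mapping = dict(zip(df["sample"], df["group"]))
    missing = [s for s in sample_ids if s not in mapping]
    if missing:
        raise ValueError(f"samples missing from label file: {missing}")
    labels = np.array([int(mapping[s]) for s in sample_ids])
    if not set(labels) <= {1, 2}:
        raise ValueError("group labels must be 1 or 2")
    return labels
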