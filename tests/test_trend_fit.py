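"""Pilot-matrix normalization, gene-wise dispersion, and trend regression."""

import numpy as np
import pandas as pd
import pytest

from nbpower import (
    DispersionTrend,
    PilotMatrix,
    fit_trend,
    genewise_dispersion,
    normalize_counts,
    simulate_pilot_matrix,
)
from nbpower.nb_core import substream
from nbpower.trend_fit import (
    GENEWISE_PHI_FLOOR,
    estimate_trend,
    genewise_dispersions,
    read_counts_tsv,
    read_labels_tsv,
)


def small_pilot(counts):
    counts = np.asarray(counts)
    S = counts.shape[1]
    labels = [1] * (S // 2) + [2] * (S - S // 2)
    return PilotMatrix(counts=counts, group_labels=np.array(labels),
                       gene_ids=[f"g{i}" for i in range(counts.shape[0])])


class TestNormalization:
    def test_identical_samples_give_unit_factors(self):
        col = np.array([[3], [10], [25], [7]])
        pilot = small_pilot(np.tile(col, (1, 6)))
        normalized, sf = normalize_counts(pilot)
        np.testing.assert_allclose(sf, 1.0, atol=1e-12)
        np.testing.assert_allclose(normalized, pilot.counts)

    def test_doubled_sample_gets_double_factor(self):
        rng = substream(3, 0)
        col = rng.poisson(50.0, 100) + 1
        counts = np.tile(col[:, None], (1, 6))
        counts[:, 0] = 2 * col  # sample 0 sequenced twice as deep
        normalized, sf = normalize_counts(small_pilot(counts))
        assert sf[0] / sf[1] == pytest.approx(2.0, rel=1e-10)
        np.testing.assert_allclose(normalized[:, 0], normalized[:, 1])

    def test_factors_have_unit_geometric_mean(self):
        rng = substream(3, 1)
        counts = rng.poisson(rng.gamma(2.0, 20.0, (200, 1)), (200, 8))
        counts[0] = 1  # guarantee an all-positive gene
        _, sf = normalize_counts(small_pilot(counts))
        assert np.exp(np.mean(np.log(sf))) == pytest.approx(1.0, abs=1e-10)

    def test_gene_permutation_invariance(self):
        rng = substream(3, 2)
        counts = rng.poisson(20.0, (150, 6)) + 1
        _, sf = normalize_counts(small_pilot(counts))
        perm = rng.permutation(150)
        _, sf_perm = normalize_counts(small_pilot(counts[perm]))
        np.testing.assert_allclose(sf, sf_perm)

    def test_no_all_positive_gene_rejected(self):
        counts = np.array([[0, 1, 1, 1], [1, 0, 1, 1]])
        with pytest.raises(ValueError):
            normalize_counts(small_pilot(counts))


class TestGenewiseDispersion:
    def test_recovers_known_dispersion(self):
        rng = substream(7, 0)
        row = rng.poisson(rng.gamma(1 / 0.5, 100 * 0.5, 200))
        labels = np.array([1] * 100 + [2] * 100)
        assert 0.4 <= genewise_dispersion(row, labels) <= 0.6

    def test_constant_row_returns_floor(self):
        labels = np.array([1, 1, 2, 2])
        assert genewise_dispersion([5, 5, 5, 5], labels) == GENEWISE_PHI_FLOOR

    def test_poisson_row_is_near_zero(self):
        rng = substream(7, 1)
        row = rng.poisson(100.0, 200)
        labels = np.array([1] * 100 + [2] * 100)
        assert genewise_dispersion(row, labels) < 0.02

    def test_requires_four_samples(self):
        with pytest.raises(ValueError):
            genewise_dispersion([1, 2, 3], np.array([1, 1, 2]))


class TestFitTrend:
    def test_noiseless_curve_recovered_exactly(self):
        means = np.logspace(np.log10(2), np.log10(2000), 300)
        disp = 0.26 + 3.65 / means
        table = pd.DataFrame({"gene_id": [f"g{i}" for i in range(300)],
                              "mean": means, "dispersion": disp})
        report = fit_trend(table)
        assert report.trend.a0 == pytest.approx(0.26, abs=1e-6)
        assert report.trend.a1 == pytest.approx(3.65, abs=1e-6)

    def test_flat_dispersions_give_zero_slope(self):
        rng = substream(7, 2)
        means = np.logspace(1, 3, 400)
        disp = 0.3 + rng.normal(0, 0.01, 400)
        table = pd.DataFrame({"gene_id": range(400), "mean": means,
                              "dispersion": disp})
        report = fit_trend(table)
        assert report.trend.a0 == pytest.approx(0.3, abs=0.02)
        assert report.trend.a1 == pytest.approx(0.0, abs=0.5)

    def test_equal_means_unidentifiable(self):
        table = pd.DataFrame({"gene_id": range(100),
                              "mean": np.full(100, 50.0),
                              "dispersion": np.full(100, 0.3)})
        with pytest.raises(ValueError):
            fit_trend(table)

    def test_too_few_usable_genes_rejected(self):
        table = pd.DataFrame({"gene_id": range(30),
                              "mean": np.linspace(5, 100, 30),
                              "dispersion": np.full(30, 0.3)})
        with pytest.raises(ValueError):
            fit_trend(table)

    def test_full_pipeline_recovery(self, trend):
        """Normalize -> gene-wise dispersions -> regression recovers the
        generating trend coefficients within the simulation tolerances."""
        pilot = simulate_pilot_matrix(2000, 20, trend, seed=41)
        report = estimate_trend(pilot)
        assert abs(report.trend.a0 - trend.a0) / trend.a0 < 0.30
        assert abs(report.trend.a1 - trend.a1) / trend.a1 < 0.50
        assert report.genes_used <= 2000

    def test_sample_permutation_within_groups_invariance(self, trend):
        pilot = simulate_pilot_matrix(400, 12, trend, seed=43)
        rep = estimate_trend(pilot)
        # permute samples inside each group
        order = np.concatenate([np.random.default_rng(0).permutation(6),
                                6 + np.random.default_rng(1).permutation(6)])
        pilot2 = PilotMatrix(counts=pilot.counts[:, order],
                             group_labels=pilot.group_labels[order],
                             gene_ids=pilot.gene_ids)
        rep2 = estimate_trend(pilot2)
        assert rep.trend.a0 == pytest.approx(rep2.trend.a0)
        assert rep.trend.a1 == pytest.approx(rep2.trend.a1)


class TestSimulatePilot:
    def test_deterministic(self, trend):
        a = simulate_pilot_matrix(10, 8, trend, seed=5)
        b = simulate_pilot_matrix(10, 8, trend, seed=5)
        assert np.array_equal(a.counts, b.counts)

    def test_zero_trend_rejected(self):
        with pytest.raises(ValueError):
            DispersionTrend(0.0, 0.0)

    def test_variance_tracks_trend(self, trend):
        """Per-gene sample variances scatter around mu + mu^2 * phi_tr(mu)."""
        pilot = simulate_pilot_matrix(1000, 100, trend, seed=6)
        m = pilot.counts.mean(axis=1)
        v = pilot.counts.var(axis=1, ddof=1)
        theo = m + m**2 * (trend.a1 / m + trend.a0)
        ratio = v / theo
        assert 0.85 < np.mean(ratio) < 1.15
        assert np.mean((ratio > 0.3) & (ratio < 3.0)) > 0.95

    def test_invalid_shapes(self, trend):
        with pytest.raises(ValueError):
            simulate_pilot_matrix(0, 8, trend)
        with pytest.raises(ValueError):
            simulate_pilot_matrix(10, 3, trend)


class TestTsvIO:
    def test_roundtrip(self, tmp_path, trend):
        pilot = simulate_pilot_matrix(60, 8, trend, seed=9)
        df = pd.DataFrame(pilot.counts, index=pilot.gene_ids,
                          columns=[f"s{i}" for i in range(8)])
        path = tmp_path / "counts.tsv"
        df.to_csv(path, sep="\t")
        counts, gene_ids, sample_ids = read_counts_tsv(path)
        assert np.array_equal(counts, pilot.counts)
        assert gene_ids == pilot.gene_ids

        lab = tmp_path / "labels.tsv"
        pd.DataFrame({"s": sample_ids, "g": pilot.group_labels}).to_csv(
            lab, sep="\t", header=False, index=False)
        labels = read_labels_tsv(lab, sample_ids)
        assert np.array_equal(labels, pilot.group_labels)

    def test_negative_count_names_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("gene\ts1\ts2\ts3\ts4\n"
                        "g1\t1\t2\t3\t4\n"
                        "g2\t1\t-2\t3\t4\n")
        with pytest.raises(ValueError, match="line 3"):
            read_counts_tsv(path)

    def test_missing_sample_label(self, tmp_path):
        path = tmp_path / "labels.tsv"
        path.write_text("s1\t1\ns2\t2\n")
        with pytest.raises(ValueError, match="missing"):
            read_labels_tsv(path, ["s1", "s2", "s3"])
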