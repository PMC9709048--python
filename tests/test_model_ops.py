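import numpy as np
import pytest
from scipy.stats import multinomial

import mixedstock as ms
from mixedstock.model import PosteriorSamples, summarize


class TestDeriveContributions:
    def test_symmetric_inputs(self):
        theta = ms.derive_contributions([0.5, 0.5], [100, 100], [0.5, 0.5])
        assert theta == pytest.approx([0.5, 0.5])

    def test_size_weighting(self):
        theta = ms.derive_contributions([0.5, 0.5], [100, 300], [0.5, 0.5])
        assert theta == pytest.approx([0.25, 0.75])

    def test_distance_weighting(self):
        theta = ms.derive_contributions([0.5, 0.5], [100, 100], [0.8, 0.2])
        assert theta == pytest.approx([0.8, 0.2])

    def test_scale_invariance_in_sizes(self):
        a = ms.derive_contributions([0.2, 0.8], [10, 40], [0.3, 0.7])
        b = ms.derive_contributions([0.2, 0.8], [1000, 4000], [0.3, 0.7])
        assert a == pytest.approx(b)
        assert a.sum() == pytest.approx(1.0)

    def test_degenerate_row_errors(self):
        with pytest.raises(ms.ValidationError, match="degenerate"):
            ms.derive_contributions([0.0, 0.0], [100, 100], [0.5, 0.5])


class TestExpectedFreqs:
    def test_single_rookery_identity(self):
        f = np.array([[0.3, 0.7]])
        assert ms.expected_mixedstock_freqs([1.0], f) == pytest.approx([0.3, 0.7])

    def test_disjoint_fixed_haplotypes(self):
        f = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert ms.expected_mixedstock_freqs([0.3, 0.7], f) == pytest.approx([0.3, 0.7])

    def test_hand_mixture(self):
        f = np.array([[0.8, 0.2], [0.4, 0.6]])
        assert ms.expected_mixedstock_freqs([0.5, 0.5], f) == pytest.approx([0.6, 0.4])

    def test_dimension_mismatch(self):
        with pytest.raises(ms.ValidationError):
            ms.expected_mixedstock_freqs([0.5, 0.5], np.ones((3, 2)) / 2)


class TestLogLikelihood:
    def _one_rookery_dataset(self):
        rook = ms.HaplotypeCountTable(("R1",), ("A",), np.array([[10]]), ms.SiteKind.ROOKERY)
        mix = ms.HaplotypeCountTable(("MS1",), ("A",), np.array([[7]]), ms.SiteKind.MIXED_STOCK)
        sizes = ms.SourceSizeTable(("R1",), np.array([100.0]), "t")
        dist = ms.EffectiveDistanceMatrix(("MS1",), ("R1",), np.array([[1000.0]]))
        return ms.MSADataset.assemble(rook, mix, sizes, dist)

    def test_degenerate_point_mass_kernel_is_zero(self):
        ds = self._one_rookery_dataset()
        ll = ms.log_likelihood(ds, f=[[1.0]], delta=[[0.6, 0.4]])
        assert ll == pytest.approx(0.0)

    def test_kernel_linear_in_counts(self, small_dataset):
        f = np.array([[0.9, 0.1], [0.2, 0.8]])
        delta = np.array([[0.5, 0.5], [0.4, 0.6]])
        ll1 = ms.log_likelihood(small_dataset, f, delta)
        doubled = ms.MSADataset.assemble(
            ms.HaplotypeCountTable(
                small_dataset.rookery_labels, small_dataset.haplotype_universe,
                2 * small_dataset.rookery_counts.counts, ms.SiteKind.ROOKERY),
            ms.HaplotypeCountTable(
                small_dataset.mixedstock_labels, small_dataset.haplotype_universe,
                2 * small_dataset.mixedstock_counts.counts, ms.SiteKind.MIXED_STOCK),
            small_dataset.sizes, small_dataset.distances)
        assert ms.log_likelihood(doubled, f, delta) == pytest.approx(2 * ll1)

    def test_matches_multinomial_pmf_oracle(self, small_dataset):
        f = np.array([[0.9, 0.1], [0.2, 0.8]])
        delta = np.array([[0.5, 0.5], [0.4, 0.6]])
        S = small_dataset.sizes.sizes
        from mixedstock.distance import scaled_inverse_distance

        P = scaled_inverse_distance(small_dataset.distances).P
        theta = ms.derive_contributions(delta[:, 0], S, P[0])
        q = ms.expected_mixedstock_freqs(theta, f)
        expected = (
            multinomial.logpmf([50, 0], 50, f[0])
            + multinomial.logpmf([0, 50], 50, f[1])
            + multinomial.logpmf([60, 40], 100, q)
        )
        got = ms.log_likelihood(small_dataset, f, delta, include_coefficient=True)
        assert got == pytest.approx(expected)

    def test_zero_probability_with_counts_is_neg_inf(self, small_dataset):
        f = np.array([[1.0, 0.0], [1.0, 0.0]])  # nobody can produce haplotype B
        delta = np.array([[0.5, 0.5], [0.5, 0.5]])
        assert ms.log_likelihood(small_dataset, f, delta) == -np.inf


def _samples_from_theta(theta_draws):
    """Wrap (C, T, M, J) theta draws in a PosteriorSamples shell."""
    C, T, M, J = theta_draws.shape
    return PosteriorSamples(
        f=np.full((C, T, J, 1), 1.0),
        delta=None,
        theta=theta_draws,
        rookery_labels=tuple(f"R{j}" for j in range(J)),
        mixedstock_labels=tuple(f"MS{i}" for i in range(M)),
        haplotype_labels=("A",),
        destination_labels=(),
    )


class TestSummarize:
    def test_constant_draws(self):
        theta = np.full((1, 50, 1, 1), 0.4)
        res = summarize(_samples_from_theta(theta), ci_level=0.95)
        row = res.summary[res.summary["kind"] == "theta"].iloc[0]
        assert (row["mean"], row["ci_lo"], row["ci_hi"]) == pytest.approx((0.4, 0.4, 0.4))
        assert row["ci_hi"] - row["ci_lo"] == pytest.approx(0.0, abs=1e-15)

    def test_median_unbiased_quantile_rule(self):
        # Hyndman & Fan type 8 by hand: position = (n + 1/3) q + 1/3 on sorted
        # draws 0.1..1.0 -> [0.13667, 0.96333] at 80% equal-tailed coverage.
        draws = (np.arange(1, 11) / 10.0).reshape(1, 10, 1, 1)
        res = summarize(_samples_from_theta(draws), ci_level=0.8)
        row = res.summary[res.summary["kind"] == "theta"].iloc[0]
        assert row["ci_lo"] == pytest.approx(0.1 + 0.36667 * 0.1, abs=1e-5)
        assert row["ci_hi"] == pytest.approx(0.9 + 0.63333 * 0.1, abs=1e-5)
        assert row["ci_lo"] <= row["mean"] <= row["ci_hi"]

    def test_theta_row_means_sum_to_one(self, quick_fit):
        _, _, samples, result = quick_fit
        assert result.theta_mean.sum(axis=1).to_numpy() == pytest.approx(
            np.ones(len(result.theta_mean)), abs=1e-9
        )

    def test_empty_draws_error(self):
        with pytest.raises(ms.ValidationError):
            summarize(_samples_from_theta(np.empty((1, 0, 1, 1))))
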