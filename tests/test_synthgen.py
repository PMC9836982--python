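"""Synthetic population: Bayes accuracies, calibration, sampling, splits."""

import numpy as np
import pytest
from scipy.stats import norm

from ceilstop import (
    LossCurveParams,
    PairedDataset,
    PopulationSpec,
    bayes_accuracy,
    calibrate_separation,
    sample_paired_dataset,
    simulate_loss_curve,
    split_grouped,
)
from ceilstop.synthgen import _largest_remainder

from conftest import random_population_spec


def spec_1d(mu1=2.0, sigma=1.0, tau=0.0, channel_noise=1.0):
    return PopulationSpec(
        dim=1,
        mu0=np.array([0.0]),
        mu1=np.array([mu1]),
        sigma=sigma,
        tau=tau,
        channel_matrix=np.array([[1.0]]),
        channel_noise=channel_noise,
        n_subjects0=4,
        n_subjects1=4,
        records_per_subject_mean=5.0,
        records_per_subject_sd=1.0,
        seed=0,
    )


class TestBayesAccuracy:
    def test_no_separation_gives_chance(self):
        assert bayes_accuracy(spec_1d(mu1=0.0), "direct") == pytest.approx(0.5)

    def test_one_dimensional_closed_form(self):
        # mu0=0, mu1=2, sd=1 => Delta=2, accuracy Phi(1)
        assert bayes_accuracy(spec_1d(), "direct") == pytest.approx(norm.cdf(1.0))

    def test_subject_effect_inflates_variance(self):
        # tau adds to the marginal covariance, shrinking the separation
        assert bayes_accuracy(spec_1d(tau=1.0), "direct") == pytest.approx(
            norm.cdf(2 / (2 * np.sqrt(2)))
        )

    def test_noisy_channel_approaches_chance(self):
        assert bayes_accuracy(spec_1d(channel_noise=1e4), "indirect") == pytest.approx(
            0.5, abs=1e-3
        )

    def test_monte_carlo_agrees_with_closed_form(self):
        spec = spec_1d()
        n = 200_000
        closed = bayes_accuracy(spec, "direct")
        mc = bayes_accuracy(spec, "direct", method="monte_carlo", n_draws=n, seed=3)
        se = np.sqrt(closed * (1 - closed) / n)
        assert abs(mc - closed) < 3 * se

    def test_singular_covariance_advises_channel_noise(self):
        spec = PopulationSpec(
            dim=2,
            mu0=np.zeros(2),
            mu1=np.ones(2),
            channel_matrix=np.array([[1.0, 0.0], [1.0, 0.0]]),  # rank 1
            channel_noise=0.0,
        )
        with pytest.raises(np.linalg.LinAlgError, match="channel_noise"):
            bayes_accuracy(spec, "indirect")

    def test_data_processing_inequality(self):
        """An indirect (transformed + noisier) channel never carries more
        class information than the direct one."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            spec = random_population_spec(rng)
            assert bayes_accuracy(spec, "indirect") <= bayes_accuracy(spec, "direct") + 1e-12


class TestCalibration:
    def test_target_mahalanobis_separation(self):
        spec = calibrate_separation(spec_1d(), 0.97)
        delta = abs(spec.mu1[0] - spec.mu0[0]) / np.sqrt(spec.marginal_var)
        assert delta == pytest.approx(2 * norm.ppf(0.97), abs=1e-9)

    @pytest.mark.parametrize("target", [0.6, 0.75, 0.9, 0.97, 0.99])
    def test_round_trip(self, target):
        spec = calibrate_separation(spec_1d(), target)
        assert bayes_accuracy(spec, "direct") == pytest.approx(target, abs=1e-6)

    def test_continuity_near_chance(self):
        spec = calibrate_separation(spec_1d(), 0.500001)
        assert abs(spec.mu1[0] - spec.mu0[0]) < 1e-3

    def test_identical_means_cannot_calibrate(self):
        with pytest.raises(ValueError, match="identical class means"):
            calibrate_separation(spec_1d(mu1=0.0), 0.9)


class TestSampling:
    def test_study_shaped_defaults(self):
        spec = PopulationSpec.study_default()
        assert (spec.n_subjects0, spec.n_subjects1) == (35, 42)
        assert spec.records_per_subject_mean == pytest.approx(22.63)
        data = sample_paired_dataset(spec)
        assert data.frame["subject_id"].nunique() == 77
        counts = data.frame.groupby("subject_id").size()
        assert counts.min() >= 1
        assert abs(counts.mean() - 22.63) < 3.0

    def test_deterministic_given_seed(self, small_spec):
        a = sample_paired_dataset(small_spec)
        b = sample_paired_dataset(small_spec)
        assert a.frame.equals(b.frame)

    def test_degenerate_noise_collapses_to_class_means(self, small_spec):
        import dataclasses

        spec = dataclasses.replace(small_spec, sigma=1e-9, tau=0.0, channel_noise=0.0)
        data = sample_paired_dataset(spec)
        for label, mu in ((0, spec.mu0), (1, spec.mu1)):
            X = data.frame[data.frame["label"] == label][data.direct_columns].to_numpy()
            assert np.allclose(X, mu, atol=1e-6)

    def test_indirect_is_transform_of_direct(self, small_spec):
        import dataclasses

        spec = dataclasses.replace(small_spec, channel_noise=0.0)
        data = sample_paired_dataset(spec)
        X = data.frame[data.direct_columns].to_numpy()
        Z = data.frame[data.indirect_columns].to_numpy()
        assert np.allclose(Z, X @ spec.channel_matrix.T)

    def test_csv_round_trip_with_sidecar(self, small_spec, tmp_path):
        data = sample_paired_dataset(small_spec)
        path = tmp_path / "data.csv"
        data.to_csv(path)
        back = PairedDataset.from_csv(path)
        assert back.dim == data.dim and back.k == data.k
        assert np.allclose(
            back.frame[data.direct_columns].to_numpy(),
            data.frame[data.direct_columns].to_numpy(),
        )
        assert back.spec is not None
        assert back.spec.seed == small_spec.seed


class TestSplit:
    def test_largest_remainder_exact_sizes(self):
        assert _largest_remainder(100, (0.80, 0.16, 0.04)) == [80, 16, 4]
        assert sum(_largest_remainder(97, (0.80, 0.16, 0.04))) == 97

    def test_record_mode_sizes(self, small_spec):
        data = sample_paired_dataset(small_spec)
        split = split_grouped(data, (0.80, 0.16, 0.04), mode="record", seed=1)
        parts = split.frame["partition"].value_counts()
        assert set(parts.index) == {"train", "val", "test_subset"}
        assert parts.sum() == len(data)  # exact partition: no loss, no duplication
        # stratified largest-remainder within each class
        for label in (0, 1):
            n = int((data.frame["label"] == label).sum())
            got = split.frame[split.frame["label"] == label]["partition"].value_counts()
            expect = _largest_remainder(n, (0.80, 0.16, 0.04))
            assert [got["train"], got["val"], got["test_subset"]] == expect

    def test_subject_mode_keeps_subjects_whole(self, small_spec):
        data = sample_paired_dataset(small_spec)
        split = split_grouped(data, (0.6, 0.2, 0.2), mode="subject", seed=1)
        spans = split.frame.groupby("subject_id")["partition"].nunique()
        assert (spans == 1).all()
        assert "test_novel" in set(split.frame["partition"])

    def test_empty_partition_is_an_error(self, small_spec):
        data = sample_paired_dataset(small_spec)
        with pytest.raises(ValueError, match="empty"):
            split_grouped(data, (0.98, 0.01, 0.01), mode="subject", seed=1)

    def test_fractions_must_sum_to_one(self, small_spec):
        data = sample_paired_dataset(small_spec)
        with pytest.raises(ValueError):
            split_grouped(data, (0.5, 0.3, 0.3), mode="record")


class TestLossCurve:
    def test_interior_minimum_matches_closed_form(self):
        params = LossCurveParams(a=0.1, b=1.0, c=0.5, tau1=10, tau2=100, horizon=200)
        trace = simulate_loss_curve(params)
        t_star = params.minimum_time()
        brute = int(np.argmin(trace.val_loss)) + 1
        assert brute == round(t_star) == 33

    def test_no_overfitting_term_is_monotone(self):
        params = LossCurveParams(a=0.2, b=1.0, c=0.0, tau1=5, tau2=50, horizon=100)
        trace = simulate_loss_curve(params)
        assert (np.diff(trace.val_loss) < 0).all()
        from ceilstop import stop_gl

        assert not stop_gl(trace).triggered

    def test_deterministic_given_seed(self):
        p = LossCurveParams(noise_sd=0.05, horizon=50, seed=9)
        a, b = simulate_loss_curve(p), simulate_loss_curve(p)
        assert np.array_equal(a.val_loss, b.val_loss)

    def test_accuracy_proxy_is_order_reversing_in_loss(self):
        trace = simulate_loss_curve(LossCurveParams(horizon=60))
        order_loss = np.argsort(trace.val_loss)
        order_acc = np.argsort(trace.val_acc)[::-1]
        assert np.array_equal(order_loss, order_acc)
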