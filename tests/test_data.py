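"""Covariance primitives: trial averaging, Bessel-corrected covariance,
pooled noise covariance, naive estimators, correlation conversion,
z-scoring."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from gsnkit import (
    ResponseData,
    covariance_to_correlation,
    naive_estimates,
    pooled_noise_covariance,
    sample_covariance,
    trial_average,
    zscore_units,
)


def _toy_c2t2():
    """n=1, c=2, t=2: condition 1 trials (0, 2), condition 2 trials
    (10, 10)."""
    return ResponseData(np.array([[[0.0, 2.0], [10.0, 10.0]]]))


class TestResponseData:
    def test_rejects_wrong_rank(self):
        with pytest.raises(ValueError, match="3-D"):
            ResponseData(np.zeros((3, 4)))

    def test_rejects_single_trial(self):
        with pytest.raises(ValueError, match="t > 1"):
            ResponseData(np.zeros((3, 4, 1)))

    def test_rejects_non_finite(self):
        vals = np.zeros((2, 3, 2))
        vals[1, 2, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            ResponseData(vals)


class TestTrialAverage:
    def test_hand_example(self):
        data = ResponseData(np.array([[[1.0, 3.0], [2.0, 4.0]]]))
        assert np.allclose(trial_average(data), [[2.0], [3.0]])

    def test_identical_trials_identity(self, rng):
        one = rng.normal(size=(4, 6))
        data = np.repeat(one[:, :, None], 3, axis=2)
        assert np.allclose(trial_average(data), one.T)

    def test_matches_loop_oracle(self, rng):
        vals = rng.normal(size=(4, 6, 3))
        expected = np.empty((6, 4))
        for j in range(6):
            for i in range(4):
                expected[j, i] = sum(vals[i, j, k] for k in range(3)) / 3
        assert np.allclose(trial_average(vals), expected, atol=1e-12)


class TestSampleCovariance:
    def test_hand_example(self):
        assert np.allclose(
            sample_covariance(np.array([[1.0, 2.0], [3.0, 4.0]])),
            [[2.0, 2.0], [2.0, 2.0]],
        )

    def test_constant_column_gives_zero_row(self, rng):
        A = rng.normal(size=(10, 3))
        A[:, 1] = 5.0
        cov = sample_covariance(A)
        assert np.allclose(cov[1, :], 0.0) and np.allclose(cov[:, 1], 0.0)

    def test_matches_two_pass_loop_oracle(self, rng):
        A = rng.normal(size=(50, 5))
        mu = [sum(A[:, j]) / 50 for j in range(5)]
        expected = np.empty((5, 5))
        for a in range(5):
            for b in range(5):
                expected[a, b] = (
                    sum((A[i, a] - mu[a]) * (A[i, b] - mu[b]) for i in range(50)) / 49
                )
        assert np.allclose(sample_covariance(A), expected, atol=1e-12)

    def test_single_observation_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            sample_covariance(np.ones((1, 3)))


class TestPooledNoiseCovariance:
    def test_hand_example(self):
        assert pooled_noise_covariance(_toy_c2t2()) == pytest.approx(
            np.array([[1.0]])
        )

    def test_zero_when_trials_identical(self, rng):
        one = rng.normal(size=(3, 5))
        data = np.repeat(one[:, :, None], 4, axis=2)
        assert np.allclose(pooled_noise_covariance(data), 0.0)

    def test_symmetric(self, simple_dataset):
        cov = pooled_noise_covariance(simple_dataset)
        assert np.max(np.abs(cov - cov.T)) <= 1e-10

    def test_mc_unbiased_for_noise_covariance(self, simple_scenario):
        from gsnkit import synthesize

        sims = np.array(
            [
                pooled_noise_covariance(synthesize(simple_scenario, 50, 5, seed=s))
                for s in range(500)
            ]
        )
        se = sims.std(axis=0, ddof=1) / np.sqrt(len(sims))
        bias = sims.mean(axis=0) - simple_scenario.noise.covariance
        assert np.all(np.abs(bias) <= 3.2 * se)


class TestNaiveEstimates:
    def test_hand_noise_example(self):
        _, noise = naive_estimates(_toy_c2t2())
        assert noise == pytest.approx(np.array([[2.0 / 3.0]]))

    def test_signal_equals_cov_of_trial_average(self, simple_dataset):
        signal, _ = naive_estimates(simple_dataset)
        assert np.allclose(
            signal, sample_covariance(trial_average(simple_dataset)), atol=1e-12
        )

    @given(
        arrays(
            np.float64,
            (3, 4, 3),
            elements=st.floats(-50, 50, allow_nan=False, width=64),
        )
    )
    def test_naive_noise_is_rescaled_pooled_noise(self, vals):
        c, t = 4, 3
        _, naive_noise = naive_estimates(vals)
        pooled = pooled_noise_covariance(vals)
        assert np.allclose(
            naive_noise, pooled * c * (t - 1) / (c * t - 1), atol=1e-12
        )


class TestCovarianceToCorrelation:
    def test_hand_example(self):
        out = covariance_to_correlation(np.array([[4.0, 1.0], [1.0, 1.0]]))
        assert np.allclose(out, [[1.0, 0.5], [0.5, 1.0]])

    def test_diagonal_maps_to_identity(self):
        out = covariance_to_correlation(np.diag([3.0, 7.0, 0.1]))
        assert np.allclose(out, np.eye(3))

    def test_zero_variance_names_offender(self):
        with pytest.raises(ValueError, match=r"unit\(s\) \[0\]"):
            covariance_to_correlation(np.array([[0.0, 0.0], [0.0, 1.0]]))


class TestZscoreUnits:
    def test_hand_example(self):
        out = zscore_units(np.array([[1.0], [2.0], [3.0]]))
        assert np.allclose(out.ravel(), [-1.0, 0.0, 1.0])

    def test_idempotent(self, rng):
        x = rng.normal(size=(40, 3))
        once = zscore_units(x)
        assert np.allclose(zscore_units(once), once, atol=1e-10)

    def test_groups_standardized_independently(self, rng):
        x = rng.normal(size=(20, 2)) * 4 + 7
        groups = np.array([0] * 10 + [1] * 10)
        out = zscore_units(x, groups)
        for grp in (out[:10], out[10:]):
            assert np.allclose(grp.mean(axis=0), 0.0, atol=1e-10)
            assert np.allclose(grp.std(axis=0, ddof=1), 1.0, atol=1e-10)

    def test_response_data_per_condition_groups(self, simple_dataset):
        c = simple_dataset.n_conditions
        groups = np.arange(c) % 2
        out = zscore_units(simple_dataset, groups)
        for gval in (0, 1):
            block = out.values[:, groups == gval, :].reshape(out.n_units, -1)
            assert np.allclose(block.mean(axis=1), 0.0, atol=1e-10)
            assert np.allclose(block.std(axis=1, ddof=1), 1.0, atol=1e-10)

    def test_zero_variance_unit_rejected(self):
        x = np.ones((5, 2))
        x[:, 1] = [1, 2, 3, 4, 5]
        with pytest.raises(ValueError, match="zero variance"):
            zscore_units(x)
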