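"""Eigenspectrum analytics: decomposition, effective dimensionality,
power-law fitting, scores, sign alignment, reliability metrics."""

import numpy as np
import pytest

from gsnkit import (
    align_pc_signs,
    cross_subject_consistency,
    effective_dimensionality,
    eigendecompose,
    fit_power_law,
    project_scores,
    splithalf_pc_reliability,
    synthesize,
)
from gsnkit.data import GaussianMoments
from gsnkit.simulate import Scenario


class TestEigendecompose:
    def test_identity(self):
        spec = eigendecompose(np.eye(10))
        assert np.allclose(spec.eigenvalues, 1.0)

    def test_block_equicorrelated_signal_spectrum(self, simple_scenario):
        spec = eigendecompose(simple_scenario.signal.covariance)
        assert np.allclose(
            spec.eigenvalues, [3, 1, 1, 1, 1, 1, 0.5, 0.5, 0.5, 0.5], atol=1e-10
        )

    def test_block_equicorrelated_noise_spectrum(self, simple_scenario):
        spec = eigendecompose(simple_scenario.noise.covariance)
        assert np.allclose(spec.eigenvalues, [6, 2, 2, 2, 2, 2, 1, 1, 1, 1], atol=1e-10)

    def test_reconstruction(self, rng):
        A = rng.normal(size=(8, 8))
        C = A @ A.T
        spec = eigendecompose(C)
        recon = (spec.eigenvectors * spec.eigenvalues) @ spec.eigenvectors.T
        assert np.linalg.norm(recon - C) <= 1e-8 * np.linalg.norm(C)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            eigendecompose(np.array([[1.0, 2.0], [0.0, 1.0]]))


class TestEffectiveDimensionality:
    @pytest.mark.parametrize(
        "spectrum, expected",
        [
            ([1, 1, 1, 1], 4.0),
            ([5, 0, 0], 1.0),
            ([3, 1, 1, 1, 1, 1, 0.5, 0.5, 0.5, 0.5], 100 / 15),
            ([6, 2, 2, 2, 2, 2, 1, 1, 1, 1], 400 / 60),
        ],
    )
    def test_known_values(self, spectrum, expected):
        assert effective_dimensionality(spectrum) == pytest.approx(expected)

    def test_scale_invariant(self, rng):
        lam = rng.uniform(0.1, 5, size=12)
        assert effective_dimensionality(3.7 * lam) == pytest.approx(
            effective_dimensionality(lam), abs=1e-12
        )

    def test_bounds(self, rng):
        for _ in range(20):
            lam = rng.uniform(0, 2, size=15)
            ed = effective_dimensionality(lam)
            assert 1.0 <= ed <= 15.0 + 1e-12

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            effective_dimensionality(np.zeros(4))


class TestFitPowerLaw:
    @pytest.mark.parametrize("n", [2, 10, 50, 200])
    def test_exact_on_exact_power_law(self, n):
        lam = np.arange(1, n + 1, dtype=float) ** -2
        slope, _, _ = fit_power_law(lam)
        assert slope == pytest.approx(-2.0, abs=1e-9)

    def test_constant_spectrum_slope_zero(self):
        slope, _, _ = fit_power_law(np.full(20, 3.0))
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_threshold_relaxes_until_two_good(self):
        slope, _, used = fit_power_law(np.array([1.0, 1e-5, 1e-6]))
        assert used.size >= 2

    def test_negative_eigenvalues_excluded(self):
        lam = np.array([4.0, 1.0, -0.5, -1.0])
        _, _, used = fit_power_law(lam)
        assert np.all(lam[used - 1] > 0)

    def test_too_few_positive_rejected(self):
        with pytest.raises(ValueError):
            fit_power_law(np.array([1.0, -1.0, 0.0]))


class TestProjectScores:
    def test_centroid_row_gives_zero(self):
        row = np.array([1.0, 2.0, 3.0])
        out = project_scores(row, row, np.eye(3))
        assert np.allclose(out, 0.0)

    def test_identity_components_return_centered(self, rng):
        rows = rng.normal(size=(5, 3))
        centroid = rows.mean(axis=0)
        assert np.allclose(project_scores(rows, centroid, np.eye(3)), rows - centroid)

    def test_matches_loop_oracle(self, rng):
        rows = rng.normal(size=(6, 4))
        centroid = rng.normal(size=4)
        comps = rng.normal(size=(4, 2))
        expected = np.empty((6, 2))
        for i in range(6):
            for k in range(2):
                expected[i, k] = sum(
                    (rows[i, j] - centroid[j]) * comps[j, k] for j in range(4)
                )
        assert np.allclose(project_scores(rows, centroid, comps), expected, atol=1e-12)


class TestSignAlignment:
    def test_negative_mean_column_flipped(self):
        comp = np.array([[-1.0, 1.0], [-2.0, 2.0]])
        out = align_pc_signs(comp)
        assert np.allclose(out, [[1.0, 1.0], [2.0, 2.0]])

    def test_identical_pair_unchanged(self, rng):
        V = rng.normal(size=(6, 3)) + 1.0  # positive means
        a, b = align_pc_signs(V, V)
        assert np.allclose(a, V) and np.allclose(b, V)

    def test_negated_partner_restored(self, rng):
        V = rng.normal(size=(6, 3))
        a, b = align_pc_signs(V, -V)
        sims = np.einsum("ij,ij->j", a, b)
        assert np.all(sims >= 0)

    def test_alignment_preserves_absolute_cosine(self, rng):
        V = rng.normal(size=(8, 4))
        W = rng.normal(size=(8, 4))
        a, b = align_pc_signs(V, W)
        before = np.abs(np.einsum("ij,ij->j", V, W))
        after = np.abs(np.einsum("ij,ij->j", a, b))
        assert np.allclose(before, after, atol=1e-12)


class TestSplithalfReliability:
    def test_low_rank_signal_gives_reliable_leading_pcs(self):
        """Noiseless rank-3 signal with well-separated eigenvalues: the
        leading principal components agree across condition halves."""
        n = 10
        V = np.linalg.qr(np.random.default_rng(0).normal(size=(n, n)))[0]
        lam = np.array([16.0, 9.0, 4.0] + [0.0] * 7)
        scen = Scenario(
            "rank3",
            GaussianMoments(np.zeros(n), (V * lam) @ V.T),
            GaussianMoments(np.zeros(n), 1e-4 * np.eye(n)),
        )
        data = synthesize(scen, c=600, t=2, seed=0)
        cos = splithalf_pc_reliability(
            data, estimator="gsn-signal", random_state=0, want_shrinkage=False
        )
        assert np.all(cos[:3] >= 0.99)

    def test_pure_noise_gives_chance_level_cosines(self):
        """Without condition structure the naive signal PCs are arbitrary
        directions; cross-half cosines hover near chance."""
        vals = []
        for s in range(3):
            rng = np.random.default_rng(s)
            data = rng.normal(size=(10, 200, 3))
            cos = splithalf_pc_reliability(data, estimator="naive", random_state=s)
            vals.extend(np.abs(cos))
        assert np.mean(vals) < 0.5

    def test_output_length(self, simple_dataset):
        cos = splithalf_pc_reliability(
            simple_dataset, estimator="naive", random_state=0
        )
        assert cos.size == min(10, 100 - 1)

    def test_unknown_estimator_rejected(self, simple_dataset):
        with pytest.raises(ValueError, match="unknown estimator"):
            splithalf_pc_reliability(simple_dataset, estimator="pca")


class TestCrossSubjectConsistency:
    def test_identical_vectors(self):
        v = np.array([1.0, 2.0, 3.0])
        out = cross_subject_consistency([v, v, v])
        assert np.allclose(out, 1.0)

    def test_single_negated_vector_recovered(self):
        v = np.array([1.0, 2.0, 3.0])
        out = cross_subject_consistency([v, -v, v])
        assert np.allclose(out, 1.0)

    def test_orthogonal_pair_untouched(self):
        out = cross_subject_consistency([np.array([1.0, 0.0]), np.array([0.0, 1.0])])
        assert out[0, 1] == pytest.approx(0.0)
        assert np.allclose(np.diag(out), 1.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            cross_subject_consistency([np.zeros(3), np.ones(3)])
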