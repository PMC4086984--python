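import numpy as np
import pytest
from sklearn.base import clone

from kneepca.correction import (
    CrosstalkCorrector,
    SubjectSide,
    TransferMatrix,
    apply_correction,
    correct_subject,
    covariance,
    eigendecompose,
    sort_eigenvectors,
    stack_cycles,
    transfer_to_posture,
)
from kneepca.exceptions import DegenerateCovarianceError
from kneepca.processing import AngleCycle
from kneepca.simulate import SyntheticConfig, generate_subject

from oracles import random_psd_3x3, symmetric_eigenvalues_closed_form


def cycles_from(X, side="right"):
    """Split an (n*101, 3) array into AngleCycles."""
    return [
        AngleCycle(X[i : i + 101], side=side, cycle_id=k)
        for k, i in enumerate(range(0, len(X), 101))
    ]


def make_subject(X, posture=None):
    return SubjectSide("S00", "right", cycles_from(X), posture=posture)


class TestStackCycles:
    def test_single_cycle_has_101_rows(self, rng):
        obs = stack_cycles(make_subject(rng.normal(size=(101, 3))))
        assert obs.X.shape == (101, 3)

    def test_five_cycles_mean_matches_summation_oracle(self, rng):
        X = rng.normal(size=(505, 3))
        obs = stack_cycles(make_subject(X))
        assert obs.X.shape == (505, 3)
        expected = np.array([sum(X[:, j]) / 505 for j in range(3)])
        assert np.allclose(obs.mean, expected, atol=1e-12)

    def test_duplicated_cycle_keeps_mean(self, rng):
        X = rng.normal(size=(101, 3))
        single = stack_cycles(make_subject(X))
        double = stack_cycles(make_subject(np.vstack([X, X])))
        assert np.allclose(single.mean, double.mean, atol=1e-12)


class TestCovariance:
    def test_constant_columns_give_zero(self):
        X = np.tile([1.0, 2.0, 3.0], (10, 1))
        assert np.allclose(covariance(X), 0.0, atol=1e-15)

    def test_toy_rows_hand_summation(self):
        """Hand computation under the 1/(n-1) divisor."""
        X = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0]], float)
        C = covariance(X, ddof=1)
        assert np.allclose(C, np.diag([2 / 3, 2 / 3, 0.0]), atol=1e-12)

    def test_exact_linear_relation_is_rank_one(self, rng):
        x = rng.normal(size=200)
        X = np.column_stack([x, 2 * x, np.zeros_like(x)])
        C = covariance(X)
        var_x = x.var(ddof=1)
        assert np.allclose(C[0, 1], 2 * var_x, atol=1e-10)
        assert np.linalg.matrix_rank(C, tol=1e-8) == 1

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            covariance(np.ones((1, 3)))


class TestEigendecompose:
    def test_diagonal_case(self):
        e = eigendecompose(np.diag([9.0, 4.0, 1.0]))
        assert np.allclose(e.eigenvalues, [9, 4, 1])
        assert np.allclose(np.abs(e.eigenvectors), np.eye(3), atol=1e-12)
        assert np.allclose(e.variance_ratio, [9 / 14, 4 / 14, 1 / 14])
        assert not e.degenerate

    def test_matches_characteristic_cubic_oracle(self, rng):
        for _ in range(300):
            C = random_psd_3x3(rng)
            e = eigendecompose(C)
            assert np.allclose(
                e.eigenvalues, symmetric_eigenvalues_closed_form(C), atol=1e-8
            )

    def test_zero_matrix_flagged_degenerate(self):
        e = eigendecompose(np.zeros((3, 3)))
        assert e.degenerate
        assert np.all(np.isnan(e.variance_ratio))

    def test_variance_fractions_sum_to_one(self, rng):
        e = eigendecompose(random_psd_3x3(rng))
        assert abs(e.variance_ratio.sum() - 1.0) < 1e-12

    def test_nonsymmetric_rejected(self):
        with pytest.raises(ValueError):
            eigendecompose(np.arange(9.0).reshape(3, 3))


class TestSortEigenvectors:
    def test_axis_aligned_in_order(self):
        e = eigendecompose(np.diag([9.0, 4.0, 1.0]))
        tm = sort_eigenvectors(e)
        assert tm.permutation == (0, 1, 2)
        assert np.allclose(tm.P, np.eye(3), atol=1e-12)

    def test_permuted_negated_columns_restored(self):
        # columns given in order (2, 3, 1) with the first column negated
        W = np.array([[0.0, 0.0, -1.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        e = eigendecompose(np.diag([1.0, 1.0, 1.0]))
        e.eigenvectors = W
        tm = sort_eigenvectors(e)
        assert np.allclose(tm.P, np.eye(3), atol=1e-12)

    def test_small_rotation_keeps_identity_assignment(self):
        from scipy.spatial.transform import Rotation

        W = Rotation.from_euler("XYZ", [5.0, -4.0, 3.0], degrees=True).as_matrix()
        tm = sort_eigenvectors(eigendecompose(W @ np.diag([9, 4, 1]) @ W.T))
        assert tm.permutation == (0, 1, 2)
        assert np.all(np.diag(tm.P) > 0.9)

    def test_choice_maximizes_diagonal_among_all_permutations(self, rng):
        """Brute-force enumeration oracle on random orthonormal bases."""
        from itertools import permutations

        from scipy.stats import special_ortho_group

        for seed in range(25):
            W = special_ortho_group.rvs(3, random_state=seed)
            e = eigendecompose(np.eye(3))
            e.eigenvectors = W
            tm = sort_eigenvectors(e)
            achieved = np.sum(np.abs(np.diag(tm.P)))
            best = max(
                sum(abs(W[i, p[i]]) for i in range(3))
                for p in permutations(range(3))
            )
            assert achieved >= best - 1e-12

    def test_tie_broken_lexicographically(self):
        # 45-degree rotation about x: permutations (0,1,2) and (0,2,1)
        # score identically; the lexicographically smaller one wins
        r = 1.0 / np.sqrt(2.0)
        W = np.array([[1.0, 0.0, 0.0], [0.0, r, -r], [0.0, r, r]])
        e = eigendecompose(np.eye(3))
        e.eigenvectors = W
        tm = sort_eigenvectors(e)
        assert tm.permutation == (0, 1, 2)


class TestCrosstalkCorrector:
    def test_sklearn_contract(self, rng):
        est = CrosstalkCorrector(ddof=0)
        assert clone(est).get_params()["ddof"] == 0
        X = rng.normal(size=(50, 3)) * [10, 2, 3]
        est.fit(X)
        assert est.transfer_matrix_.shape == (3, 3)
        assert est.transform(X).shape == (50, 3)
        back = est.inverse_transform(est.transform(X))
        assert np.allclose(back, X, atol=1e-10)

    def test_output_channels_uncorrelated(self, rng):
        X = rng.normal(size=(400, 3)) @ rng.normal(size=(3, 3)) + [30, 5, -2]
        Xc = CrosstalkCorrector().fit_transform(X)
        C = np.corrcoef(Xc.T)
        off = np.abs(C[~np.eye(3, dtype=bool)])
        assert np.max(off) < 1e-10

    def test_total_variance_conserved(self, rng):
        X = rng.normal(size=(300, 3)) * [15, 3, 4]
        est = CrosstalkCorrector().fit(X)
        before = X.var(axis=0, ddof=1).sum()
        after = est.transform(X).var(axis=0, ddof=1).sum()
        assert abs(before - after) < 1e-9 * before

    def test_rank_deficient_input_raises(self):
        x = np.linspace(0, 10, 50)
        X = np.column_stack([x, np.full_like(x, 2.0), np.full_like(x, 3.0)])
        with pytest.raises(DegenerateCovarianceError):
            CrosstalkCorrector().fit(X)

    def test_wrong_width_rejected(self, rng):
        with pytest.raises(ValueError):
            CrosstalkCorrector().fit(rng.normal(size=(50, 4)))


class TestApplyCorrection:
    def test_identity_transfer_is_identity(self, rng):
        cyc = AngleCycle(rng.normal(size=(101, 3)))
        tm = TransferMatrix(np.eye(3), (0, 1, 2), np.ones(3))
        assert np.array_equal(apply_correction(cyc, tm).samples, cyc.samples)

    def test_linear_coupling_collapses_to_zero_variance(self):
        """beta = 0.2*alpha exactly: the corrected frontal-plane channel
        carries no variance, matching a direct projection oracle."""
        t = np.linspace(0, 2 * np.pi, 101)
        alpha = 30 + 20 * np.sin(t)
        X = np.column_stack([alpha, 0.2 * alpha, 3 * np.cos(3 * t)])
        s = make_subject(X)
        result = correct_subject(s)
        corrected = result.corrected_cycles[0].samples
        assert corrected[:, 1].var(ddof=1) < 1e-9
        # projection oracle: corrected abduction lies along the null
        # direction (-0.2, 1)/norm of the rank-deficient (alpha, beta) cloud
        null = np.array([-0.2, 1.0, 0.0]) / np.hypot(0.2, 1.0)
        expected = X @ null
        sign = np.sign(null @ result.transfer.P[:, 1])
        assert np.allclose(corrected[:, 1], sign * expected, atol=1e-8)


class TestCorrectSubject:
    def test_already_diagonal_covariance_gives_identity(self, rng):
        X = np.column_stack(
            [
                30 + 15 * np.sin(np.linspace(0, 2 * np.pi, 101)),
                2 * np.cos(np.linspace(0, 4 * np.pi, 101)),
                5 + np.sin(np.linspace(0, 6 * np.pi, 101)),
            ]
        )
        # orthogonal harmonics: covariance is (near-)diagonal
        result = correct_subject(make_subject(X))
        assert result.transfer.permutation == (0, 1, 2)
        assert np.allclose(result.transfer.P, np.eye(3), atol=0.05)

    def test_corrected_cycle_count_and_shape(self, rng):
        s = make_subject(rng.normal(size=(303, 3)) * [10, 2, 3])
        result = correct_subject(s)
        assert len(result.corrected_cycles) == 3
        assert all(c.samples.shape == (101, 3) for c in result.corrected_cycles)

    def test_misaligned_subject_abduction_variance_shrinks(self):
        cfg = SyntheticConfig(misalignment_range=None, misalignment_deg=10.0)
        s, _ = generate_subject(cfg, 0, "right")
        result = correct_subject(s)
        before = np.vstack([c.samples for c in s.cycles])[:, 1].var(ddof=1)
        after = np.vstack([c.samples for c in result.corrected_cycles])[:, 1].var(ddof=1)
        assert after < before

    def test_recovers_true_flexion_within_one_degree(self):
        cfg = SyntheticConfig(
            misalignment_range=None,
            misalignment_deg=10.0,
            noise_sd=0.0,
            flexion_rotation_coupling=0.0,
            n_cycles=2,
        )
        s, truth = generate_subject(cfg, 0, "right")
        result = correct_subject(s)
        flex_true = truth.true_cycles[0].samples[:, 0]
        flex_corr = result.corrected_cycles[0].samples[:, 0]
        assert np.sqrt(np.mean((flex_corr - flex_true) ** 2)) < 1.0

    def test_idempotent(self):
        cfg = SyntheticConfig(misalignment_range=None, misalignment_deg=12.0)
        s, _ = generate_subject(cfg, 3, "left")
        first = correct_subject(s)
        s2 = SubjectSide(s.subject, s.side, first.corrected_cycles)
        second = correct_subject(s2)
        assert np.allclose(second.transfer.P, np.eye(3), atol=1e-8)
        for a, b in zip(first.corrected_cycles, second.corrected_cycles):
            assert np.allclose(a.samples, b.samples, atol=1e-8)


class TestPostureTransfer:
    def test_identity_leaves_posture(self):
        tm = TransferMatrix(np.eye(3), (0, 1, 2), np.ones(3))
        p = np.array([5.0, 4.0, 3.0])
        assert np.array_equal(transfer_to_posture(p, tm), p)

    @pytest.mark.parametrize("deformity", [5.0, 0.0])
    def test_deformity_recovered_through_misalignment(self, deformity):
        cfg = SyntheticConfig(
            misalignment_range=None,
            misalignment_deg=10.0,
            abduction_offset=deformity,
        )
        s, truth = generate_subject(cfg, 1, "right")
        result = correct_subject(s)
        corrected_abd = result.corrected_posture[1]
        assert abs(corrected_abd - deformity) < 0.5
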