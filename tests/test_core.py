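"""Covariance accumulation, key-matrix assembly and the Q-J pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

import qjrmsd as q
from qjrmsd.core import accumulate_single_pass, build_key_matrix, rmsd_from_lambda

DOUBLE = q.PrecisionPolicy.double()
MIXED = q.PrecisionPolicy.mixed()
SINGLE = q.PrecisionPolicy.single()


def two_pass_summary(A, B):
    """Independent oracle: center first, then form the products."""
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    return Ac.T @ Bc, float((Ac * Ac).sum()), float((Bc * Bc).sum())


class TestAccumulateSinglePass:
    def test_triangle_fixture_matches_two_pass_oracle(self):
        A = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], float)
        s = accumulate_single_pass(A, A, DOUBLE)
        R_expected = np.array([[2 / 3, -1 / 3, 0], [-1 / 3, 2 / 3, 0], [0, 0, 0]])
        assert s.gA == pytest.approx(4 / 3, rel=1e-12)
        assert s.gB == pytest.approx(4 / 3, rel=1e-12)
        np.testing.assert_allclose(s.R, R_expected, atol=1e-12)
        R2, gA2, gB2 = two_pass_summary(A, A)
        np.testing.assert_allclose(s.R, R2, atol=1e-12)
        assert s.gA == pytest.approx(gA2, rel=1e-12)

    def test_translation_of_either_set_cancels(self, rng):
        A = rng.normal(0, 5, (30, 3))
        B = rng.normal(0, 5, (30, 3))
        s0 = accumulate_single_pass(A, B, DOUBLE)
        s1 = accumulate_single_pass(A + [100.0, -3.0, 7.0], B, DOUBLE)
        s2 = accumulate_single_pass(A, A + [4.0, 4.0, 4.0], DOUBLE)
        s3 = accumulate_single_pass(A, A, DOUBLE)
        np.testing.assert_allclose(s1.R, s0.R, rtol=1e-9, atol=1e-9)
        assert s1.gA == pytest.approx(s0.gA, rel=1e-9)
        np.testing.assert_allclose(s2.R, s3.R, rtol=1e-9, atol=1e-9)
        assert s2.gB == pytest.approx(s3.gB, rel=1e-9)

    def test_single_point_is_its_own_barycenter(self):
        s = accumulate_single_pass([[5, 5, 5]], [[-2, 0, 9]], DOUBLE)
        np.testing.assert_array_equal(s.R, np.zeros((3, 3)))
        assert s.gA == 0.0 and s.gB == 0.0 and s.n_atoms == 1

    def test_errors(self):
        with pytest.raises(q.CorrespondenceError):
            accumulate_single_pass(np.zeros((3, 3)), np.zeros((4, 3)))
        with pytest.raises(q.EmptyInputError):
            accumulate_single_pass(np.zeros((0, 3)), np.zeros((0, 3)))
        bad = np.zeros((2, 3))
        bad[0, 0] = np.nan
        with pytest.raises((q.NumericError, ValueError)):
            q.CoordinateSet(bad)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        arrays(np.float64, (7, 3), elements=st.floats(-100, 100)),
        arrays(np.float64, (7, 3), elements=st.floats(-100, 100)),
    )
    def test_single_pass_equals_two_pass(self, A, B):
        s = accumulate_single_pass(A, B, DOUBLE)
        R2, gA2, gB2 = two_pass_summary(A, B)
        scale = max(1.0, np.abs(R2).max(), gA2, gB2)
        np.testing.assert_allclose(s.R, R2, atol=1e-9 * scale)
        assert abs(s.gA - gA2) <= 1e-9 * scale
        assert abs(s.gB - gB2) <= 1e-9 * scale
        # Cauchy-Schwarz bound on every covariance entry
        assert np.all(np.abs(s.R) <= np.sqrt(s.gA * s.gB) + 1e-9 * scale)


class TestKeyMatrix:
    def test_identity_covariance(self):
        s = q.CovarianceSummary(R=np.eye(3), gA=3.0, gB=3.0, n_atoms=3)
        F = build_key_matrix(s, DOUBLE).F
        np.testing.assert_array_equal(F, np.diag([3.0, -1.0, -1.0, -1.0]))

    def test_zero_covariance(self):
        s = q.CovarianceSummary(R=np.zeros((3, 3)), gA=0.0, gB=0.0, n_atoms=2)
        np.testing.assert_array_equal(build_key_matrix(s, DOUBLE).F, np.zeros((4, 4)))

    def test_traceless_and_bitwise_symmetric(self, rng):
        for _ in range(20):
            R = rng.normal(0, 10, (3, 3))
            s = q.CovarianceSummary(R=R, gA=1.0, gB=1.0, n_atoms=2)
            F = build_key_matrix(s, DOUBLE).F
            assert np.array_equal(F, F.T)
            assert abs(np.trace(F)) <= 1e-12 * np.abs(F).max()

    def test_mixed_policy_rounds_to_binary32(self, rng):
        R = rng.normal(0, 10, (3, 3))
        s = q.CovarianceSummary(R=R, gA=1.0, gB=1.0, n_atoms=2)
        F = build_key_matrix(s, MIXED).F
        assert F.dtype == np.float32
        F64 = build_key_matrix(s, DOUBLE).F
        np.testing.assert_array_equal(F, F64.astype(np.float32))

    def test_nonfinite_rejected(self):
        R = np.full((3, 3), np.inf)
        s = q.CovarianceSummary(R=R, gA=1.0, gB=1.0, n_atoms=2)
        with pytest.raises(q.NumericError):
            build_key_matrix(s)


class TestRmsdFromLambda:
    def test_exact_zero_radicand(self):
        assert rmsd_from_lambda(2.0, 2.0, 2.0, 5) == 0.0

    def test_negative_rounding_residue_clamped(self):
        v = rmsd_from_lambda(1.0, 1.0, 1.0 + 5e-13, 3)
        assert v == 0.0 and not np.isnan(v)

    def test_matches_rot_oracle_on_triangle_pair(self, rng):
        A = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], float)
        B = A + rng.normal(0, 0.3, A.shape)
        s = accumulate_single_pass(A, B, DOUBLE)
        lam = q.jacobi_eig4(build_key_matrix(s, DOUBLE)).eigenvalues[0]
        expected = q.rmsd_rot(A, B)[0]
        assert rmsd_from_lambda(s.gA, s.gB, lam, 3) == pytest.approx(expected, abs=1e-10)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            rmsd_from_lambda(1.0, 1.0, 0.5, 0)


class TestRmsdQj:
    def test_self_comparison_is_zero(self, rng):
        A = rng.normal(0, 8, (25, 3))
        assert q.rmsd_qj(A, A, DOUBLE) <= 1e-6
        for policy in (MIXED, SINGLE):
            # binary32 key matrix leaves at most a ulp-scale residue in the
            # radicand: below the 0.01 A reporting resolution, never NaN
            v = q.rmsd_qj(A, A, policy)
            assert np.isfinite(v) and v < 5e-3

    def test_rigid_motion_fully_recovered(self):
        A = np.random.default_rng(3).normal(0, 8, (40, 3))
        Rz = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        B = A @ Rz.T + np.array([1.0, 2.0, 3.0])
        assert q.rmsd_qj(A, B, DOUBLE) <= 1e-6

    def test_symmetry_and_rigid_invariance(self, rng, small_pairs):
        for a, b in small_pairs[:8]:
            r = q.rmsd_qj(a, b, DOUBLE)
            assert q.rmsd_qj(b, a, DOUBLE) == pytest.approx(r, abs=1e-9)
            t = rng.uniform(-30, 30, 3)
            assert q.rmsd_qj(a.coords + t, b, DOUBLE) == pytest.approx(r, abs=1e-9)
            v = rng.normal(size=4)
            Q = q.quaternion_to_rotation(v / np.linalg.norm(v))
            assert q.rmsd_qj(a.coords @ Q.T, b, DOUBLE) == pytest.approx(r, abs=1e-6)

    def test_agrees_with_rotational_oracle(self, small_pairs):
        for a, b in small_pairs:
            assert abs(q.rmsd_qj(a, b, DOUBLE) - q.rmsd_rot(a, b)[0]) < 1e-6

    def test_never_exceeds_unsuperposed_deviation(self, small_pairs):
        for a, b in small_pairs:
            naive = np.sqrt(((a.coords - b.coords) ** 2).sum() / len(a))
            assert q.rmsd_qj(a, b, DOUBLE) <= naive + 1e-6

    def test_lambda_max_bounded_by_mean_centered_norm(self, small_pairs):
        for a, b in small_pairs:
            s = accumulate_single_pass(a, b, DOUBLE)
            lam = q.jacobi_eig4(build_key_matrix(s, DOUBLE)).eigenvalues[0]
            assert lam <= (s.gA + s.gB) / 2 + 1e-9 * (s.gA + s.gB)

    def test_mixed_policy_tracks_double_on_divergent_pairs(self, rng):
        # decoy-like divergence (>~0.5 A): binary32 key matrix changes the
        # RMSD only at the 1e-5 A level
        for _ in range(10):
            A = rng.uniform(-12, 12, (200, 3))
            B = A + rng.normal(0, 1.0, A.shape)
            assert q.rmsd_qj(A, B, MIXED) == pytest.approx(
                q.rmsd_qj(A, B, DOUBLE), abs=2e-4
            )
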