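"""Singular systems, truncated pseudoinverse, and projector algebra."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hallumap import (
    LinearOperator,
    OperatorSVD,
    TruncationSpec,
    choose_truncation,
    compute_svd,
    decompose,
    materialize,
    project_meas,
    project_null,
    truncated_pinv_apply,
)
from hallumap.operators import load_svd, save_svd


def _svd_with_mu(mu):
    """Diagonal operator with prescribed squared singular values."""
    sigma = np.sqrt(np.asarray(mu, dtype=float))
    n = sigma.size
    return OperatorSVD(
        sigma=sigma, U=np.eye(n, dtype=complex), V=np.eye(n, dtype=complex),
        shape_in=(n,), shape_out=(n,),
    )


class TestComputeSVD:
    def test_identity_operator(self):
        svd = compute_svd(LinearOperator.from_matrix(np.eye(4)))
        assert svd.rank == 4
        np.testing.assert_allclose(svd.sigma, np.ones(4))

    def test_zero_operator(self):
        svd = compute_svd(LinearOperator.from_matrix(np.zeros((3, 5))))
        assert svd.rank == 0
        assert svd.sigma.size == 0

    def test_matches_dense_oracle(self, dense_op):
        svd = compute_svd(dense_op)
        oracle = np.linalg.svd(materialize(dense_op), compute_uv=False)
        np.testing.assert_allclose(svd.sigma, oracle[: svd.rank], atol=1e-10)

    def test_reconstruction_and_orthonormality(self, dense_op, rng):
        svd = compute_svd(dense_op)
        H = svd.V @ np.diag(svd.sigma) @ svd.U.conj().T
        x = rng.normal(size=16) + 1j * rng.normal(size=16)
        np.testing.assert_allclose(
            (H @ x).reshape(dense_op.shape_out), dense_op.apply(x.reshape(16)), atol=1e-10
        )
        np.testing.assert_allclose(svd.U.conj().T @ svd.U, np.eye(svd.rank), atol=1e-10)
        np.testing.assert_allclose(svd.V.conj().T @ svd.V, np.eye(svd.rank), atol=1e-10)

    def test_contract_mismatch_raises(self):
        op = LinearOperator(
            shape_in=(4,), shape_out=(3,),
            apply=lambda x: np.zeros(2), adjoint_apply=lambda y: np.zeros(4),
        )
        with pytest.raises(ValueError, match="apply produced shape"):
            compute_svd(op)


class TestChooseTruncation:
    @pytest.mark.parametrize(
        "mu, epsilon, expected_P",
        [
            ((4, 1, 0.01), np.sqrt(2), 2),   # 1/eps^2 = 0.5 sits between mu_2 and mu_3
            ((4, 1, 0.01), 1e9, 3),          # huge tolerance keeps every mode
            ((4, 1, 0.01), 0.1, 0),          # 1/eps^2 = 100 rejects all modes
            ((4, 1, 0.01), 1.0, 1),          # tie mu_2 = 1/eps^2 = 1 is EXCLUDED
        ],
    )
    def test_threshold_rule(self, mu, epsilon, expected_P):
        assert choose_truncation(_svd_with_mu(mu), epsilon).P == expected_P

    def test_epsilon_must_be_positive(self):
        with pytest.raises(ValueError):
            choose_truncation(_svd_with_mu((1,)), 0.0)


class TestTruncatedPinv:
    def test_identity_returns_measurement(self, rng):
        svd = compute_svd(LinearOperator.from_matrix(np.eye(5)))
        trunc = choose_truncation(svd, 1e6)
        g = rng.normal(size=5)
        np.testing.assert_allclose(truncated_pinv_apply(svd, trunc, g), g, atol=1e-12)

    def test_single_mode(self, dense_op, rng):
        svd = compute_svd(dense_op)
        trunc = choose_truncation(svd, 1e6)
        c = 2.3 - 0.7j
        g = (svd.V[:, 0] * c).reshape(dense_op.shape_out)
        expected = (c / svd.sigma[0]) * svd.U[:, 0]
        np.testing.assert_allclose(
            np.ravel(truncated_pinv_apply(svd, trunc, g)), expected, atol=1e-10
        )

    def test_matches_truncated_matrix_pinv_oracle(self, dense_op, rng):
        svd = compute_svd(dense_op)
        P = 3
        trunc = TruncationSpec(epsilon=1.0 / svd.sigma[P], P=P)  # mu_P > 1/eps^2 by construction
        H_P = svd.V[:, :P] @ np.diag(svd.sigma[:P]) @ svd.U[:, :P].conj().T
        g = rng.normal(size=6) + 1j * rng.normal(size=6)
        oracle = np.linalg.pinv(H_P) @ g
        np.testing.assert_allclose(
            np.ravel(truncated_pinv_apply(svd, trunc, g.reshape(6))), oracle, atol=1e-10
        )

    def test_P_zero_returns_zero_object(self, dense_op, caplog):
        svd = compute_svd(dense_op)
        trunc = TruncationSpec(epsilon=1e-8, P=0)
        out = truncated_pinv_apply(svd, trunc, np.ones(6, dtype=complex).reshape(6))
        assert np.all(out == 0)


class TestProjectors:
    @pytest.fixture
    def system(self, dense_op):
        svd = compute_svd(dense_op)
        trunc = TruncationSpec(epsilon=1.0, P=4)
        return svd, trunc

    def test_meas_keeps_leading_vector(self, system):
        svd, trunc = system
        u1 = svd.U[:, 0].reshape(svd.shape_in)
        np.testing.assert_allclose(project_meas(svd, trunc, u1), u1, atol=1e-10)

    def test_meas_kills_trailing_vector(self, system):
        svd, trunc = system
        u_next = svd.U[:, trunc.P].reshape(svd.shape_in)
        assert np.abs(project_meas(svd, trunc, u_next)).max() < 1e-10
        np.testing.assert_allclose(
            project_null(svd, trunc, u_next), u_next, atol=1e-10
        )

    def test_meas_equals_explicit_matrix_oracle(self, system, dense_op, rng):
        svd, trunc = system
        H = materialize(dense_op)
        H_P_pinv = svd.U[:, : trunc.P] @ np.diag(1 / svd.sigma[: trunc.P]) @ svd.V[:, : trunc.P].conj().T
        theta = rng.normal(size=16) + 1j * rng.normal(size=16)
        oracle = H_P_pinv @ (H @ theta)
        np.testing.assert_allclose(
            np.ravel(project_meas(svd, trunc, theta.reshape(svd.shape_in))), oracle, atol=1e-10
        )

    def test_complementarity_orthogonality_idempotence(self, system, rng):
        svd, trunc = system
        theta = (rng.normal(size=16) + 1j * rng.normal(size=16)).reshape(svd.shape_in)
        tm, tn = decompose(svd, trunc, theta)
        np.testing.assert_allclose(tm + tn, theta, atol=1e-12)
        assert abs(np.vdot(tm, tn)) < 1e-10 * np.linalg.norm(tm) * np.linalg.norm(tn)
        np.testing.assert_allclose(project_meas(svd, trunc, tm), tm, atol=1e-10)
        np.testing.assert_allclose(project_null(svd, trunc, tn), tn, atol=1e-10)

    def test_stability_bound(self, dense_op, rng):
        """Truncated pinv is 1/sigma_P-Lipschitz in the measurements."""
        svd = compute_svd(dense_op)
        for P in (1, 3, 6):
            trunc = TruncationSpec(epsilon=1.0, P=P)
            lip = 1.0 / svd.sigma[P - 1]
            for _ in range(50):
                g1 = rng.normal(size=6) + 1j * rng.normal(size=6)
                g2 = rng.normal(size=6) + 1j * rng.normal(size=6)
                d_obj = np.linalg.norm(
                    truncated_pinv_apply(svd, trunc, g1.reshape(6))
                    - truncated_pinv_apply(svd, trunc, g2.reshape(6))
                )
                assert d_obj <= lip * np.linalg.norm(g1 - g2) * (1 + 1e-12)

    def test_null_amplification_bound(self, dense_op, rng):
        """For vectors in the generalized null space, ||H s|| <= sigma_{P+1} ||s||."""
        svd = compute_svd(dense_op)
        trunc = TruncationSpec(epsilon=1.0, P=3)
        sigma_next = svd.sigma[trunc.P]
        for _ in range(20):
            theta = (rng.normal(size=16) + 1j * rng.normal(size=16)).reshape(svd.shape_in)
            s = project_null(svd, trunc, theta)
            Hs = dense_op.apply(s)
            assert np.linalg.norm(Hs) <= sigma_next * np.linalg.norm(s) * (1 + 1e-10)

    def test_true_null_space_when_P_equals_R(self, rng):
        """With exact zero modes and P = R, the null projection maps into ker(H)."""
        basis = np.linalg.qr(rng.normal(size=(8, 8)))[0]
        H = basis[:, :5] @ np.diag([3.0, 2.0, 1.5, 1.0, 0.5]) @ np.linalg.qr(
            rng.normal(size=(8, 8))
        )[0][:, :5].conj().T
        op = LinearOperator.from_matrix(H)
        svd = compute_svd(op)
        assert svd.rank == 5
        trunc = choose_truncation(svd, 1e6)
        assert trunc.P == svd.rank
        theta = (rng.normal(size=8) + 1j * rng.normal(size=8)).reshape(op.shape_in)
        tn = project_null(svd, trunc, theta)
        assert np.linalg.norm(op.apply(tn)) < 1e-10


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_adjoint_consistency_and_linearity(seed):
    """<Hx, y> == <x, H^dagger y> and H(ax+by) == aHx + bHy for random operators."""
    rng = np.random.default_rng(seed)
    m, n = rng.integers(2, 9, size=2)
    op = LinearOperator.from_matrix(rng.normal(size=(m, n)) + 1j * rng.normal(size=(m, n)))
    x = rng.normal(size=n) + 1j * rng.normal(size=n)
    xb = rng.normal(size=n) + 1j * rng.normal(size=n)
    y = rng.normal(size=m) + 1j * rng.normal(size=m)
    lhs = np.vdot(y, op.apply(x.reshape(op.shape_in)))
    rhs = np.vdot(op.adjoint_apply(y.reshape(op.shape_out)), x)
    assert abs(lhs - rhs) < 1e-10 * (1 + abs(lhs))
    a, b = 1.7 - 0.3j, -0.4 + 2.1j
    np.testing.assert_allclose(
        op.apply((a * x + b * xb).reshape(op.shape_in)),
        a * op.apply(x.reshape(op.shape_in)) + b * op.apply(xb.reshape(op.shape_in)),
        atol=1e-10,
    )


def test_svd_archive_round_trip(tmp_path, dense_op):
    svd = compute_svd(dense_op)
    trunc = choose_truncation(svd, 1.0)
    path = tmp_path / "svd.npz"
    save_svd(path, svd, trunc)
    svd2, trunc2 = load_svd(path)
    np.testing.assert_array_equal(svd.sigma, svd2.sigma)
    np.testing.assert_array_equal(svd.U, svd2.U)
    np.testing.assert_array_equal(svd.V, svd2.V)
    assert (trunc2.P, trunc2.epsilon) == (trunc.P, trunc.epsilon)
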