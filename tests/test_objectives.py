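"""Contrastive objectives and Hopfield retrieval against hand and loop oracles."""

import numpy as np
import pytest

from cellmol.nn import Tensor
from cellmol.objectives import (
    bilinear_infonce,
    bilinear_score,
    hopfield_retrieve,
    infoloob_loss,
    infoloob_loss_t,
    infonce_loss,
    infonce_loss_t,
    similarity_matrix,
)


def _unit_rows(rng, n, d):
    A = rng.normal(size=(n, d))
    return A / np.linalg.norm(A, axis=1, keepdims=True)


def infonce_loop_oracle(X, Z, tau_inv):
    """Naive O(N^2) evaluation of the symmetric InfoNCE objective."""
    N = X.shape[0]
    total = 0.0
    for i in range(N):
        num = np.exp(tau_inv * X[i] @ Z[i])
        den_row = sum(np.exp(tau_inv * X[i] @ Z[j]) for j in range(N))
        den_col = sum(np.exp(tau_inv * X[j] @ Z[i]) for j in range(N))
        total += -np.log(num / den_row) - np.log(num / den_col)
    return total / N


def hopfield_loop_oracle(memory, queries, beta):
    out = []
    for q in np.atleast_2d(queries):
        w = np.exp(beta * memory @ q)
        w = w / w.sum()
        r = w @ memory
        out.append(r / np.linalg.norm(r))
    return np.array(out)


def infoloob_loop_oracle(X, Z, beta, tau_inv):
    U_x = hopfield_loop_oracle(X, X, beta)
    U_z = hopfield_loop_oracle(X, Z, beta)
    V_x = hopfield_loop_oracle(Z, X, beta)
    V_z = hopfield_loop_oracle(Z, Z, beta)
    N = X.shape[0]
    total = 0.0
    for i in range(N):
        num_u = np.exp(tau_inv * U_x[i] @ U_z[i])
        den_u = sum(np.exp(tau_inv * U_x[i] @ U_z[j])
                    for j in range(N) if j != i)
        num_v = np.exp(tau_inv * V_x[i] @ V_z[i])
        den_v = sum(np.exp(tau_inv * V_x[j] @ V_z[i])
                    for j in range(N) if j != i)
        total += -np.log(num_u / den_u) - np.log(num_v / den_v)
    return total / N


class TestSimilarityMatrix:
    def test_orthonormal_identity(self):
        X = np.eye(3)
        assert np.allclose(similarity_matrix(X, X), np.eye(3))

    def test_antipodal_pair(self):
        x = np.array([[1.0, 0.0]])
        z = np.array([[-1.0, 0.0]])
        assert similarity_matrix(x, z)[0, 0] == pytest.approx(-1.0)

    def test_matches_double_loop(self):
        rng = np.random.default_rng(3)
        X, Z = _unit_rows(rng, 3, 4), _unit_rows(rng, 3, 4)
        S = similarity_matrix(X, Z)
        for i in range(3):
            for j in range(3):
                assert S[i, j] == pytest.approx(X[i] @ Z[j])

    def test_rejects_unnormalized(self):
        with pytest.raises(ValueError, match="unit-norm"):
            similarity_matrix(2 * np.eye(2), np.eye(2))

    def test_rejects_dim_mismatch(self):
        with pytest.raises(ValueError):
            similarity_matrix(np.eye(2), np.eye(3))


class TestInfoNCE:
    def test_single_pair_is_zero(self):
        x = np.array([[1.0, 0.0]])
        assert infonce_loss(x, x, 14.3) == pytest.approx(0.0)

    def test_two_orthonormal_pairs_closed_form(self):
        X = np.eye(2)
        assert infonce_loss(X, X, 1.0) == pytest.approx(
            2 * np.log(1 + np.exp(-1)), abs=1e-12)

    @pytest.mark.parametrize("n", [2, 5, 16])
    def test_matches_loop_oracle(self, n):
        rng = np.random.default_rng(n)
        X, Z = _unit_rows(rng, n, 8), _unit_rows(rng, n, 8)
        assert infonce_loss(X, Z, 14.3) == pytest.approx(
            infonce_loop_oracle(X, Z, 14.3), abs=1e-6)

    def test_decreases_when_unmatched_similarity_drops(self):
        # pushing an un-matched pair apart shrinks the softmax denominator
        rng = np.random.default_rng(0)
        X, Z = _unit_rows(rng, 4, 6), _unit_rows(rng, 4, 6)
        base = infonce_loss(X, Z, 5.0)
        Z2 = Z.copy()
        Z2[1] = -X[0] / np.linalg.norm(X[0])  # antipodal to query 0
        assert infonce_loss(X, Z2, 5.0) != base  # sanity: changed
        S = similarity_matrix(X, Z)
        S2 = S.copy()
        S2[0, 1] = S[0, 1] - 0.5  # lower one un-matched entry directly
        def from_scores(S, t):
            d = np.diag(S)
            lse_r = np.log(np.exp(t * S).sum(axis=1))
            lse_c = np.log(np.exp(t * S).sum(axis=0))
            return float(np.mean(lse_r - t * d) + np.mean(lse_c - t * d))
        assert from_scores(S2, 5.0) < from_scores(S, 5.0)

    def test_invariant_under_joint_row_permutation(self):
        rng = np.random.default_rng(1)
        X, Z = _unit_rows(rng, 6, 5), _unit_rows(rng, 6, 5)
        perm = rng.permutation(6)
        assert infonce_loss(X[perm], Z[perm], 7.0) == pytest.approx(
            infonce_loss(X, Z, 7.0), abs=1e-10)

    def test_nonnegative_and_finite_at_high_inverse_temperature(self):
        rng = np.random.default_rng(2)
        X, Z = _unit_rows(rng, 8, 4), _unit_rows(rng, 8, 4)
        value = infonce_loss(X, Z, 30.0)
        assert np.isfinite(value) and value >= 0.0

    def test_rejects_unnormalized(self):
        with pytest.raises(ValueError):
            infonce_loss(np.eye(2) * 3, np.eye(2), 1.0)


class TestHopfieldRetrieve:
    def test_beta_zero_returns_normalized_memory_mean(self):
        memory = np.eye(2)
        out = hopfield_retrieve(memory, np.array([[0.6, 0.8]]), 0.0)
        assert np.allclose(out, np.full((1, 2), 1 / np.sqrt(2)))

    def test_large_beta_returns_nearest_pattern(self):
        memory = np.eye(2)
        out = hopfield_retrieve(memory, np.array([[1.0, 0.0]]), 1e4)
        assert np.allclose(out, [[1.0, 0.0]], atol=1e-4)

    def test_finite_beta_matches_softmax_oracle(self):
        rng = np.random.default_rng(4)
        memory = _unit_rows(rng, 3, 5)
        queries = _unit_rows(rng, 4, 5)
        assert np.allclose(hopfield_retrieve(memory, queries, 1.0),
                           hopfield_loop_oracle(memory, queries, 1.0))

    def test_output_rows_unit_norm(self):
        rng = np.random.default_rng(5)
        memory = _unit_rows(rng, 6, 4)
        out = hopfield_retrieve(memory, _unit_rows(rng, 10, 4), 22.0)
        assert np.allclose(np.linalg.norm(out, axis=1), 1.0)

    def test_retrieval_in_convex_cone_of_memory(self):
        # pre-normalization retrieval is a convex combination of rows
        rng = np.random.default_rng(6)
        memory = _unit_rows(rng, 3, 3)
        q = _unit_rows(rng, 1, 3)
        w = np.exp(22.0 * memory @ q[0]); w /= w.sum()
        r = w @ memory
        coeffs = np.linalg.solve(memory.T, r)
        assert (coeffs >= -1e-9).all() and coeffs.sum() == pytest.approx(1.0)

    def test_rejects_empty_memory(self):
        with pytest.raises(ValueError):
            hopfield_retrieve(np.empty((0, 3)), np.ones((1, 3)), 1.0)


class TestInfoLOOB:
    def test_rejects_single_pair(self):
        x = np.array([[1.0, 0.0]])
        with pytest.raises(ValueError, match="N >= 2"):
            infoloob_loss(x, x, 22.0, 30.0)

    def test_two_orthonormal_pairs_beta_zero_collapses_to_zero(self):
        # all retrievals equal the common normalized mean, so numerator and
        # the single leave-one-out denominator term coincide
        X = np.eye(2)
        assert infoloob_loss(X, X, 0.0, 30.0) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("n,beta", [(3, 1.0), (8, 22.0), (16, 5.0)])
    def test_matches_loop_oracle(self, n, beta):
        rng = np.random.default_rng(n)
        X, Z = _unit_rows(rng, n, 6), _unit_rows(rng, n, 6)
        assert infoloob_loss(X, Z, beta, 14.3) == pytest.approx(
            infoloob_loop_oracle(X, Z, beta, 14.3), abs=1e-6)

    def test_large_beta_matches_nearest_pattern_oracle(self):
        # beta -> inf retrieval snaps every query to its most similar stored
        # pattern; the limiting loss follows from those hard assignments
        rng = np.random.default_rng(9)
        X, Z = _unit_rows(rng, 5, 4), _unit_rows(rng, 5, 4)
        big = infoloob_loss(X, Z, 1e6, 3.0)
        nearest = lambda M, q: M[np.argmax(M @ q)]
        U_x = np.array([nearest(X, x) for x in X])  # self-queries: X itself
        U_z = np.array([nearest(X, z) for z in Z])
        V_x = np.array([nearest(Z, x) for x in X])
        V_z = np.array([nearest(Z, z) for z in Z])
        t, N = 3.0, 5
        total = 0.0
        for i in range(N):
            num_u = np.exp(t * U_x[i] @ U_z[i])
            den_u = sum(np.exp(t * U_x[i] @ U_z[j])
                        for j in range(N) if j != i)
            num_v = np.exp(t * V_x[i] @ V_z[i])
            den_v = sum(np.exp(t * V_x[j] @ V_z[i])
                        for j in range(N) if j != i)
            total += -np.log(num_u / den_u) - np.log(num_v / den_v)
        assert big == pytest.approx(total / N, abs=1e-3)

    def test_finite_for_extreme_inputs(self):
        X = np.eye(4)
        assert np.isfinite(infoloob_loss(X, X, 1e4, 30.0))

    def test_memory_hook_accepts_external_memories(self):
        rng = np.random.default_rng(11)
        X, Z = _unit_rows(rng, 4, 5), _unit_rows(rng, 4, 5)
        M = _unit_rows(rng, 7, 5)
        external = infoloob_loss(X, Z, 2.0, 5.0, memory_x=M, memory_z=M)
        assert np.isfinite(external)
        assert external != pytest.approx(infoloob_loss(X, Z, 2.0, 5.0))


class TestBilinear:
    def test_identity_matrix_unit_vector(self):
        x = np.array([1.0, 0.0])
        assert bilinear_score(x, x, np.eye(2)) == pytest.approx(1.0)

    def test_zero_weights_uniform_softmax(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(5, 3))
        Z = rng.normal(size=(5, 4))
        W = np.zeros((3, 4))
        assert bilinear_infonce(X, Z, W, 2.0) == pytest.approx(2 * np.log(5))

    def test_matches_explicit_matrix_algebra(self):
        rng = np.random.default_rng(13)
        x, z = rng.normal(size=2), rng.normal(size=2)
        W = rng.normal(size=(2, 2))
        expected = sum(x[i] * W[i, j] * z[j] for i in range(2) for j in range(2))
        assert bilinear_score(x, z, W) == pytest.approx(expected)

    def test_rejects_shape_mismatch(self):
        with pytest.raises(ValueError):
            bilinear_score(np.ones(3), np.ones(2), np.eye(2))


class TestDifferentiableCounterparts:
    """The autograd losses compute the same values as the numpy references."""

    def test_infonce_parity(self):
        rng = np.random.default_rng(20)
        X, Z = _unit_rows(rng, 7, 5), _unit_rows(rng, 7, 5)
        assert infonce_loss_t(Tensor(X), Tensor(Z), 14.3).item() == \
            pytest.approx(infonce_loss(X, Z, 14.3), abs=1e-9)

    def test_infoloob_parity(self):
        rng = np.random.default_rng(21)
        X, Z = _unit_rows(rng, 6, 5), _unit_rows(rng, 6, 5)
        assert infoloob_loss_t(Tensor(X), Tensor(Z), 22.0, 30.0).item() == \
            pytest.approx(infoloob_loss(X, Z, 22.0, 30.0), abs=1e-8)
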