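"""Unbiased HSIC and linear CKA against independent oracles.

The HSIC oracle evaluates the three estimator terms with explicit index
loops; CKA invariances (orthogonal transforms, isotropic scaling, symmetry,
boundedness) are checked on randomized inputs.
"""

import numpy as np
import pytest
from scipy.stats import ortho_group

from xakd.errors import DegenerateDataError, ValidationError
from xakd.similarity import (
    GramMatrix,
    linear_cka,
    minibatch_cka,
    stage_cka_matrix,
    unbiased_hsic,
)


def hsic_loop_oracle(K, L):
    """Three-term unbiased estimator via explicit index sums."""
    n = K.shape[0]
    Kt = K - np.diag(np.diag(K))
    Lt = L - np.diag(np.diag(L))
    t1 = sum(Kt[i, j] * Lt[j, i] for i in range(n) for j in range(n))
    s_k = sum(Kt[i, j] for i in range(n) for j in range(n))
    s_l = sum(Lt[i, j] for i in range(n) for j in range(n))
    t2 = s_k * s_l / ((n - 1) * (n - 2))
    t3 = (2.0 / (n - 2)) * sum(
        Kt[i, j] * Lt[j, k] for i in range(n) for j in range(n) for k in range(n)
    )
    return (t1 + t2 - t3) / (n * (n - 3))


class TestUnbiasedHsic:
    def test_matches_loop_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(8, 17))
            X, Y = rng.normal(size=(n, 3)), rng.normal(size=(n, 3))
            K, L = X @ X.T, Y @ Y.T
            assert abs(unbiased_hsic(K, L) - hsic_loop_oracle(K, L)) < 1e-10

    def test_symmetry_and_linearity(self, rng):
        X, Y = rng.normal(size=(10, 4)), rng.normal(size=(10, 5))
        K, L = X @ X.T, Y @ Y.T
        assert unbiased_hsic(K, L) == pytest.approx(unbiased_hsic(L, K))
        assert unbiased_hsic(3.0 * K, L) == pytest.approx(3.0 * unbiased_hsic(K, L))

    def test_mean_near_zero_for_independent_views(self):
        # unbiasedness: average over many seeds within 3 standard errors of 0
        vals = []
        for seed in range(200):
            r = np.random.default_rng(seed)
            X, Y = r.normal(size=(16, 4)), r.normal(size=(16, 4))
            vals.append(unbiased_hsic(X @ X.T, Y @ Y.T))
        vals = np.array(vals)
        assert abs(vals.mean()) < 3 * vals.std(ddof=1) / np.sqrt(len(vals))

    def test_preconditions(self, rng):
        X = rng.normal(size=(3, 2))
        with pytest.raises(ValidationError):
            unbiased_hsic(X @ X.T, X @ X.T)  # n < 4
        M = rng.normal(size=(6, 6))  # asymmetric
        with pytest.raises(ValidationError):
            unbiased_hsic(M, M.T @ M)
        with pytest.raises(ValidationError):
            GramMatrix(M)


class TestLinearCka:
    def test_self_similarity_is_one(self, rng):
        X = rng.normal(size=(20, 6))
        assert linear_cka(X, X) == pytest.approx(1.0, abs=1e-8)

    def test_orthogonal_and_scaling_invariance(self, rng):
        for _ in range(10):
            X = rng.normal(size=(16, 5))
            Y = rng.normal(size=(16, 7))
            Q = ortho_group.rvs(5, random_state=np.random.RandomState(int(rng.integers(1 << 30))))
            assert linear_cka(X, X @ Q) == pytest.approx(1.0, abs=1e-8)
            assert linear_cka(2.7 * X, Y) == pytest.approx(linear_cka(X, Y), abs=1e-8)
            assert linear_cka(X, Y) == pytest.approx(linear_cka(Y, X), abs=1e-8)
            assert linear_cka(X, Y) <= 1 + 1e-6

    def test_one_dimensional_limit_approaches_r_squared(self):
        r, n = 0.6, 2000
        rng = np.random.default_rng(42)
        cov = np.array([[1.0, r], [r, 1.0]])
        z = rng.normal(size=(n, 2)) @ np.linalg.cholesky(cov).T
        sample_r2 = np.corrcoef(z[:, 0], z[:, 1])[0, 1] ** 2
        assert linear_cka(z[:, :1], z[:, 1:]) == pytest.approx(sample_r2, abs=0.05)

    def test_degenerate_representation_raises(self):
        const = np.ones((8, 3))
        with pytest.raises(DegenerateDataError):
            linear_cka(const, const)


class TestMinibatchCka:
    def test_single_batch_reduces_to_plain_cka(self, rng):
        X, Y = rng.normal(size=(24, 5)), rng.normal(size=(24, 6))
        assert minibatch_cka([X], [Y]) == pytest.approx(linear_cka(X, Y))

    def test_repeated_batch_equals_single(self, rng):
        X, Y = rng.normal(size=(16, 5)), rng.normal(size=(16, 6))
        assert minibatch_cka([X] * 3, [Y] * 3) == pytest.approx(minibatch_cka([X], [Y]))

    def test_two_batches_approximate_full_batch(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(240, 8))
        Y = X @ rng.normal(size=(8, 6)) + 0.5 * rng.normal(size=(240, 6))
        full = linear_cka(X, Y)
        halves = minibatch_cka([X[:120], X[120:]], [Y[:120], Y[120:]])
        assert halves == pytest.approx(full, abs=0.05)

    def test_mismatched_batches_rejected(self, rng):
        with pytest.raises(ValidationError):
            minibatch_cka([rng.normal(size=(8, 3))], [])


class TestGramIdentity:
    def test_vec_dot_equals_trace_equals_frobenius(self, rng):
        # <vec(XX'), vec(YY')> = tr(XX'YY') = ||Y'X||_F^2
        for _ in range(10):
            X = rng.normal(size=(12, 4))
            Y = rng.normal(size=(12, 6))
            K, L = X @ X.T, Y @ Y.T
            lhs = K.ravel() @ L.ravel()
            mid = np.trace(K @ L)
            rhs = np.linalg.norm(Y.T @ X, "fro") ** 2
            assert lhs == pytest.approx(mid, rel=1e-8)
            assert mid == pytest.approx(rhs, rel=1e-8)


class TestStageCkaMatrix:
    def test_self_pair_single_layer(self, rng):
        from xakd.probes import RepresentationMatrix

        X = RepresentationMatrix(rng.normal(size=(10, 4)), 0, "teacher", "gap")
        cka = stage_cka_matrix([X], [X], (0,), (0,), stage="early")
        assert cka.values.shape == (1, 1)
        assert cka.values[0, 0] == pytest.approx(1.0, abs=1e-8)

    def test_planted_rotated_copy_is_the_unique_maximum(self, rng):
        X0, X1 = rng.normal(size=(20, 6)), rng.normal(size=(20, 6))
        Q = ortho_group.rvs(6, random_state=1)
        teacher = [X0, X1]
        student = [rng.normal(size=(20, 6)), X1 @ Q]  # plant (1, 1)
        cka = stage_cka_matrix(teacher, student, (0, 1), (0, 1), stage="mid")
        assert cka.values[1, 1] == pytest.approx(1.0, abs=1e-8)
        mask = np.ones((2, 2), bool)
        mask[1, 1] = False
        assert np.all(cka.values[mask] < 1.0 - 1e-3)
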