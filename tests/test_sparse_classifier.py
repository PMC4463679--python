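"""Gaussian weighting, the BPDN solver, residuals and classification."""

import numpy as np
import pytest

from _oracles import bpdn_oracle, feasible_bpdn_instance
from ppisparse.errors import DataValidationError, ParameterError, SolverError
from ppisparse.sparse_classifier import (
    SparseRepresentationClassifier,
    gaussian_weight,
    solve_l1,
)


class TestGaussianWeight:
    def test_zero_distance_is_one(self, rng):
        x = rng.normal(size=6)
        assert gaussian_weight(x, x, sigma=3.0) == 1.0

    def test_symmetry(self, rng):
        x, y = rng.normal(size=5), rng.normal(size=5)
        assert gaussian_weight(x, y, 2.0) == gaussian_weight(y, x, 2.0)

    def test_matches_direct_arithmetic_at_sigma_50(self):
        """At sigma=50 and small distances, exp(-r^2/5000) ~ 1 - r^2/5000."""
        x = np.array([0.2, 0.1, 0.0])
        y = np.array([0.0, 0.0, 0.1])
        r2 = 0.2**2 + 0.1**2 + 0.1**2
        w = gaussian_weight(x, y, sigma=50.0)
        assert w == pytest.approx(np.exp(-r2 / 5000.0), rel=1e-12)
        assert w == pytest.approx(1 - r2 / 5000.0, abs=1e-7)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ParameterError, match="sigma"):
            gaussian_weight(np.ones(3), np.zeros(3), 0.0)


class TestSolveL1:
    def test_zero_query_gives_zero_code(self, rng):
        X = rng.normal(size=(4, 6))
        X /= np.linalg.norm(X, axis=0)
        np.testing.assert_array_equal(solve_l1(X, np.zeros(4), 0.05), np.zeros(6))

    def test_single_atom_identity(self, rng):
        """A query equal to a dictionary column is recovered as (almost)
        the corresponding unit coefficient vector."""
        X = rng.normal(size=(6, 5))
        X /= np.linalg.norm(X, axis=0)
        alpha = solve_l1(X, X[:, 2].copy(), epsilon=1e-9)
        expected = np.zeros(5)
        expected[2] = 1.0
        np.testing.assert_allclose(alpha, expected, atol=1e-6)

    def test_matches_convex_program_oracle(self):
        """30 seeded random feasible instances agree with a generic convex
        solver in l1 objective and both stay feasible."""
        rng = np.random.default_rng(202)
        for _ in range(30):
            X, y, eps = feasible_bpdn_instance(rng)
            alpha = solve_l1(X, y, eps)
            assert np.linalg.norm(y - X @ alpha) <= eps * (1 + 1e-6)
            ref = bpdn_oracle(X, y, eps)
            assert np.abs(alpha).sum() == pytest.approx(
                np.abs(ref).sum(), abs=1e-4
            )

    def test_homogeneous_scaling(self, rng):
        """Scaling the query and epsilon together scales the code."""
        X = rng.normal(size=(5, 8))
        X /= np.linalg.norm(X, axis=0)
        y = rng.normal(size=5)
        a1 = solve_l1(X, y, 0.1)
        a2 = solve_l1(X, 3.0 * y, 0.3)
        np.testing.assert_allclose(a2, 3.0 * a1, atol=1e-8)

    def test_infeasible_instance_raises(self):
        X = np.array([[1.0], [0.0]])
        y = np.array([0.0, 1.0])  # orthogonal to the only atom
        with pytest.raises(SolverError, match="infeasible"):
            solve_l1(X, y, epsilon=0.05)

    def test_parameter_and_shape_errors(self, rng):
        X = rng.normal(size=(4, 3))
        with pytest.raises(ParameterError, match="epsilon"):
            solve_l1(X, np.ones(4), 0.0)
        with pytest.raises(DataValidationError, match="mismatch"):
            solve_l1(X, np.ones(5), 0.05)


def _toy_model(rng, n_per_class=6, d=8, n_classes=3, spread=0.2):
    means = np.eye(n_classes, d) * 2.0
    X = np.vstack(
        [rng.normal(means[c], spread, (n_per_class, d)) for c in range(n_classes)]
    )
    y = np.repeat(np.arange(n_classes), n_per_class)
    return np.abs(X), y


class TestClassResiduals:
    def test_zero_alpha_gives_query_norm(self, rng):
        X, y = _toy_model(rng)
        clf = SparseRepresentationClassifier(mode="src").fit(X, y)
        q = rng.normal(size=8)
        g = clf.class_residuals(np.zeros(X.shape[0]), q)
        np.testing.assert_allclose(g, np.full(3, np.linalg.norm(q)))

    def test_matches_direct_matrix_arithmetic(self, rng):
        """Residuals equal brute-force ||y - X' delta_k(alpha)|| computed
        with plain numpy on the same weighted dictionary."""
        X, y = _toy_model(rng)
        clf = SparseRepresentationClassifier(mode="wsrc", sigma=2.0).fit(X, y)
        q = np.abs(rng.normal(size=8))
        code = clf.classify_one(q)
        Xw = clf.dictionary_ * code.weights
        for k in range(3):
            masked = code.alpha.copy()
            masked[y != k] = 0.0
            direct = np.linalg.norm(q - Xw @ masked)
            assert code.residuals[k] == pytest.approx(direct, abs=1e-12)
        assert code.residuals.min() >= 0
        assert code.predicted_class == np.argmin(code.residuals)


class TestClassify:
    def test_memorization(self, rng):
        X, y = _toy_model(rng)
        clf = SparseRepresentationClassifier(epsilon=1e-6).fit(X, y)
        for i in (0, 7, 13):
            q = X[i] / np.linalg.norm(X[i])  # a stored unit column
            assert clf.classify_one(q).predicted_class == y[i]

    def test_wsrc_equals_src_at_huge_sigma(self, rng):
        X, y = _toy_model(rng, n_per_class=10)
        queries = np.abs(rng.normal(size=(15, 8)))
        src = SparseRepresentationClassifier(mode="src").fit(X, y)
        wsrc = SparseRepresentationClassifier(mode="wsrc", sigma=1e9).fit(X, y)
        np.testing.assert_array_equal(src.predict(queries), wsrc.predict(queries))

    def test_two_cluster_recovery(self):
        """Orthogonal-subspace Gaussian clusters in 8 dimensions, means
        separated by 5x the noise scale, 40 train / 40 test."""
        rng = np.random.default_rng(3)
        d, c = 8, 5 / np.sqrt(8)
        mu0 = np.r_[np.full(4, c), np.zeros(4)]
        mu1 = np.r_[np.zeros(4), np.full(4, c)]
        Xtr = np.vstack([rng.normal(mu0, 1, (20, d)), rng.normal(mu1, 1, (20, d))])
        ytr = np.r_[np.zeros(20, int), np.ones(20, int)]
        Xte = np.vstack([rng.normal(mu0, 1, (20, d)), rng.normal(mu1, 1, (20, d))])
        yte = np.r_[np.zeros(20, int), np.ones(20, int)]
        clf = SparseRepresentationClassifier(mode="wsrc").fit(Xtr, ytr)
        assert (clf.predict(Xte) == yte).mean() >= 0.95

    def test_decision_invariant_to_column_permutation(self, rng):
        X, y = _toy_model(rng, n_per_class=8)
        queries = np.abs(rng.normal(size=(10, 8)))
        perm = rng.permutation(X.shape[0])
        a = SparseRepresentationClassifier(mode="wsrc", sigma=5.0).fit(X, y)
        b = SparseRepresentationClassifier(mode="wsrc", sigma=5.0).fit(X[perm], y[perm])
        np.testing.assert_array_equal(a.predict(queries), b.predict(queries))

    def test_src_scale_consistency(self, rng):
        """For unweighted SRC, scaling the query with epsilon relaxed
        proportionally leaves the decision unchanged."""
        X, y = _toy_model(rng)
        q = np.abs(rng.normal(size=8))
        a = SparseRepresentationClassifier(mode="src", epsilon=0.05).fit(X, y)
        b = SparseRepresentationClassifier(mode="src", epsilon=0.25).fit(X, y)
        assert a.classify_one(q).predicted_class == b.classify_one(5 * q).predicted_class

    def test_zero_weight_underflow_falls_back_to_src(self, rng):
        X, y = _toy_model(rng)
        far_query = np.full(8, 1e4)  # much farther than sigma allows
        clf = SparseRepresentationClassifier(mode="wsrc", sigma=0.01, epsilon=10).fit(X, y)
        with pytest.warns(RuntimeWarning, match="underflowed"):
            code = clf.classify_one(far_query)
        np.testing.assert_array_equal(code.weights, np.ones(X.shape[0]))

    def test_dimension_mismatch_rejected(self, rng):
        X, y = _toy_model(rng)
        clf = SparseRepresentationClassifier().fit(X, y)
        with pytest.raises(DataValidationError, match="dimension"):
            clf.classify_one(np.ones(5))


class TestModelPersistence:
    def test_save_load_round_trip(self, tmp_path, rng):
        X, y = _toy_model(rng)
        clf = SparseRepresentationClassifier(mode="wsrc", sigma=7.0, epsilon=0.02)
        clf.fit(X, y)
        path = tmp_path / "model.npz"
        clf.save(path, metadata={"profile": "CP(5)", "n": 1})
        loaded, meta = SparseRepresentationClassifier.load(path)
        assert (loaded.mode, loaded.sigma, loaded.epsilon) == ("wsrc", 7.0, 0.02)
        assert meta == {"profile": "CP(5)", "n": 1}
        np.testing.assert_array_equal(loaded.dictionary_, clf.dictionary_)
        q = np.abs(rng.normal(size=8))
        assert loaded.classify_one(q).predicted_class == clf.classify_one(q).predicted_class


def test_constructor_validates_parameters():
    with pytest.raises(ParameterError):
        SparseRepresentationClassifier(mode="svm")
    with pytest.raises(ParameterError):
        SparseRepresentationClassifier(sigma=-1)
    with pytest.raises(ParameterError):
        SparseRepresentationClassifier(epsilon=0)
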