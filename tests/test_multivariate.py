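import numpy as np
import pytest

from cryosperm import (
    KNearestNeighbors,
    LinearDiscriminant,
    PrincipalComponents,
    knn_predict,
    lda_fit,
    lda_predict,
    pca_fit,
    pca_transform,
)


def brute_force_discriminants(X, y, classes, ridge=1e-6):
    """Independent evaluation of δ_c(x) = xᵀΣ⁻¹μ_c − ½μ_cᵀΣ⁻¹μ_c + log π_c."""
    X = np.asarray(X, float)
    n, p = X.shape
    mus, pis, scatter = [], [], np.zeros((p, p))
    for c in classes:
        Xc = X[np.asarray(y) == c]
        mu = Xc.mean(axis=0)
        mus.append(mu)
        pis.append(len(Xc) / n)
        for row in Xc:
            d = (row - mu)[:, None]
            scatter += d @ d.T
    sigma = scatter / (n - len(classes))
    sigma = sigma + ridge * np.trace(sigma) / p * np.eye(p)
    inv = np.linalg.inv(sigma)
    out = np.empty((n, len(classes)))
    for i, x in enumerate(X):
        for j, (mu, pi) in enumerate(zip(mus, pis)):
            out[i, j] = x @ inv @ mu - 0.5 * mu @ inv @ mu + np.log(pi)
    return out


class TestPCA:
    def test_rank_one_data_explained_by_first_component(self):
        x1 = np.linspace(0, 1, 10)
        X = np.c_[x1, 2 * x1]
        model = pca_fit(X, 1)
        assert model.explained_fraction_[0] == pytest.approx(1.0, abs=1e-10)

    def test_components_orthonormal(self):
        rng = np.random.default_rng(0)
        model = pca_fit(rng.normal(size=(15, 6)), 4)
        G = model.components_ @ model.components_.T
        assert np.allclose(G, np.eye(4), atol=1e-8)

    def test_explained_variance_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = rng.integers(4, 21)
            p = rng.integers(2, 11)
            X = rng.normal(size=(n, p)) * rng.uniform(0.5, 3, size=p)
            k = int(min(n - 1, p))
            model = pca_fit(X, k)
            eig = np.sort(np.linalg.eigvalsh(np.cov(X.T, ddof=1)))[::-1]
            assert np.allclose(model.explained_variance_, eig[:k], atol=1e-8)

    def test_matches_sklearn_cross_check(self):
        sk = pytest.importorskip("sklearn.decomposition")
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 8))
        ours = pca_fit(X, 5)
        ref = sk.PCA(n_components=5).fit(X)
        assert np.allclose(ours.explained_variance_, ref.explained_variance_, atol=1e-8)
        assert np.allclose(np.abs(ours.components_), np.abs(ref.components_), atol=1e-8)

    def test_full_reconstruction_recovers_matrix(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 5))
        model = pca_fit(X, 5)
        assert np.allclose(model.inverse_transform(model.transform(X)), X, atol=1e-8)

    def test_score_variances_equal_explained_variance(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(25, 6))
        model = pca_fit(X, 3)
        S = pca_transform(model, X)
        assert np.allclose(S.var(axis=0, ddof=1), model.explained_variance_, atol=1e-8)

    def test_zero_variance_input_gives_zero_scores(self):
        X = np.ones((6, 3)) * 5
        model = pca_fit(X, 2)
        assert np.allclose(model.transform(X), 0.0)
        assert np.allclose(model.explained_fraction_, 0.0)

    def test_held_out_rows_project_without_refit(self):
        rng = np.random.default_rng(5)
        model = pca_fit(rng.normal(size=(10, 4)), 2)
        center = model.center_.copy()
        out = model.transform(rng.normal(size=(3, 4)) + 100)
        assert np.all(np.isfinite(out))
        assert np.array_equal(model.center_, center)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(10, 4))
        model = pca_fit(X, 3)
        for comp in model.components_:
            assert comp[np.argmax(np.abs(comp))] > 0

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError):
            pca_fit(np.zeros((3, 5)), 4)
        model = pca_fit(np.random.default_rng(7).normal(size=(6, 4)), 2)
        with pytest.raises(ValueError):
            model.transform(np.zeros((2, 5)))


class TestLDA:
    def test_separable_clouds_classified_perfectly(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(-5, 1, (20, 3)), rng.normal(5, 1, (20, 3))])
        y = np.array(["a"] * 20 + ["b"] * 20, dtype=object)
        model = lda_fit(X, y)
        assert np.all(lda_predict(model, X) == y)

    def test_identical_classes_default_to_higher_prior(self):
        X = np.tile(np.array([[0.0, 0.0], [1.0, 1.0]]), (3, 1))
        y = np.array(["a", "a", "a", "a", "b", "b"], dtype=object)
        model = lda_fit(X, y)
        assert np.all(lda_predict(model, np.array([[0.5, 0.5]])) == "a")

    def test_equidistant_point_breaks_tie_by_label_order(self):
        X = np.array([[-1.0, 0.0], [-1.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
        y = np.array(["left", "left", "right", "right"], dtype=object)
        model = lda_fit(X, y)
        assert lda_predict(model, np.array([[0.0, 0.5]]))[0] == "left"

    def test_four_point_toy_matches_hand_oracle(self):
        X = np.array([[0.0, 0.0], [1.0, 0.0], [3.0, 2.0], [4.0, 2.0]])
        y = np.array(["a", "a", "b", "b"], dtype=object)
        model = lda_fit(X, y)
        oracle = brute_force_discriminants(X, y, ["a", "b"])
        assert np.allclose(model.decision_function(X), oracle, atol=1e-10)

    def test_twelve_point_three_class_matches_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(12, 4)) + np.repeat([[0], [3], [-3]], 4, axis=0)
        y = np.array(["a"] * 4 + ["b"] * 4 + ["c"] * 4, dtype=object)
        model = lda_fit(X, y)
        oracle = brute_force_discriminants(X, y, ["a", "b", "c"])
        assert np.allclose(model.decision_function(X), oracle, atol=1e-10)

    def test_isotropic_covariance_reduces_to_nearest_mean(self):
        # both classes share an isotropic sample covariance and equal priors
        cross = np.array([[1.0, 0], [-1.0, 0], [0, 1.0], [0, -1.0]])
        X = np.vstack([cross, cross + [10, 0]])
        y = np.array(["a"] * 4 + ["b"] * 4, dtype=object)
        model = lda_fit(X, y)
        rng = np.random.default_rng(2)
        Q = rng.normal(0, 5, (50, 2)) + [5, 0]
        nearest = np.where(
            np.linalg.norm(Q - [0, 0], axis=1) <= np.linalg.norm(Q - [10, 0], axis=1),
            "a",
            "b",
        )
        assert np.all(lda_predict(model, Q) == nearest)

    def test_fit_order_invariant(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 4))
        y = np.array(list("abc") * 10, dtype=object)
        m1 = lda_fit(X, y)
        perm = rng.permutation(30)
        m2 = lda_fit(X[perm], y[perm])
        assert np.allclose(m1.class_means_, m2.class_means_)
        assert np.allclose(m1.pooled_covariance_, m2.pooled_covariance_)

    def test_matches_sklearn_predictions_on_toy(self):
        sk = pytest.importorskip("sklearn.discriminant_analysis")
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(i * 3, 1, (15, 3)) for i in range(3)])
        y = np.array(["a"] * 15 + ["b"] * 15 + ["c"] * 15, dtype=object)
        ours = lda_fit(X, y).predict(X)
        ref = sk.LinearDiscriminantAnalysis().fit(X, y.astype(str)).predict(X)
        assert np.all(ours.astype(str) == ref)

    def test_single_class_and_missing_class_rejected(self):
        X = np.zeros((4, 2))
        with pytest.raises(ValueError):
            lda_fit(X, np.array(["a"] * 4, dtype=object))
        with pytest.raises(ValueError, match="'c'"):
            LinearDiscriminant().fit(X, np.array(["a", "a", "b", "b"], dtype=object), classes=["a", "b", "c"])


class TestKNN:
    def test_k1_self_classification_is_perfect(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 3))
        y = np.array(list("ab") * 10, dtype=object)
        assert np.all(knn_predict(X, y, X, k=1) == y)

    def test_k_equals_n_votes_majority(self):
        X = np.arange(5.0)[:, None]
        y = np.array(["a", "a", "a", "b", "b"], dtype=object)
        assert np.all(knn_predict(X, y, np.array([[100.0]]), k=5) == "a")

    def test_hand_example_matches_exhaustive_sort(self):
        train = np.array([[0.0], [1.0], [2.0], [10.0], [11.0]])
        y = np.array(["a", "a", "b", "b", "b"], dtype=object)
        # query at 1.5: 3 nearest are {1:a, 2:b, 0:a} -> 'a'
        assert knn_predict(train, y, np.array([[1.5]]), k=3)[0] == "a"
        # query at 6: 3 nearest are {2:b, 10:b, 1:a} -> 'b'
        assert knn_predict(train, y, np.array([[6.0]]), k=3)[0] == "b"

    def test_vote_tie_broken_by_mean_distance(self):
        train = np.array([[0.0], [0.5], [3.0], [4.0]])
        y = np.array(["a", "a", "b", "b"], dtype=object)
        # k=4 at x=1: tie 2-2, mean distance a = 0.75 < b = 2.5 -> 'a'
        assert knn_predict(train, y, np.array([[1.0]]), k=4)[0] == "a"

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            knn_predict(np.zeros((3, 1)), np.array(list("abc"), dtype=object), np.zeros((1, 1)), k=4)
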