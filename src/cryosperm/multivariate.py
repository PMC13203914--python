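"""In-repo multivariate estimators: PCA, linear discriminant analysis, kNN.

Small sklearn-style estimators (``fit`` / ``transform`` / ``predict``,
``get_params`` / ``set_params``, fitted attributes with a trailing
underscore) that compose with sklearn pipelines without importing sklearn.
PCA is computed by singular-value decomposition of the centred matrix with
a deterministic sign convention; LDA uses class-conditional Gaussians with
a pooled within-class covariance and a small scale-aware ridge.
"""

from __future__ import annotations

import numpy as np


class _Estimator:
    """Minimal get_params/set_params support keyed off __init__ arguments."""

    _param_names: tuple[str, ...] = ()

    def get_params(self, deep: bool = True) -> dict:
        return {name: getattr(self, name) for name in self._param_names}

    def set_params(self, **params):
        for name, value in params.items():
            if name not in self._param_names:
                raise ValueError(f"unknown parameter {name!r}")
            setattr(self, name, value)
        return self


class PrincipalComponents(_Estimator):
    """Principal component analysis via SVD of the centred matrix.

    Components carry a deterministic sign: the largest-magnitude loading
    coefficient of each component is positive (first such index on ties).

    Attributes (after fit)
    ----------------------
    components_ : (n_components, n_features) orthonormal loadings
    center_ : per-feature mean removed before projection
    explained_variance_ : per-component variance (n-1 denominator)
    explained_fraction_ : per-component fraction of total variance
    """

    _param_names = ("n_components",)

    def __init__(self, n_components: int):
        self.n_components = n_components

    def fit(self, X, y=None) -> "PrincipalComponents":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D matrix")
        n, p = X.shape
        k = int(self.n_components)
        if k < 1 or k > min(n - 1, p):
            raise ValueError(
                f"n_components={k} must lie in [1, min(rows-1, features)] = "
                f"[1, {min(n - 1, p)}]"
            )
        self.center_ = X.mean(axis=0)
        Xc = X - self.center_
        _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        comps = Vt[:k].copy()
        for i in range(k):
            j = int(np.argmax(np.abs(comps[i])))
            if comps[i, j] < 0:
                comps[i] = -comps[i]
        self.components_ = comps
        ev_all = s**2 / (n - 1)
        self.explained_variance_ = ev_all[:k]
        total = float(ev_all.sum())
        self.explained_fraction_ = (
            ev_all[:k] / total if total > 0 else np.zeros(k)
        )
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.center_.shape[0]:
            raise ValueError(
                f"feature count {X.shape[-1]} does not match fit ({self.center_.shape[0]})"
            )
        return (X - self.center_) @ self.components_.T

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).transform(X)

    def inverse_transform(self, scores) -> np.ndarray:
        scores = np.asarray(scores, dtype=float)
        return scores @ self.components_ + self.center_


class LinearDiscriminant(_Estimator):
    """Multiclass LDA with pooled within-class covariance and empirical priors.

    The pooled covariance is Σ = Σ_c (n_c − 1) S_c / (N − C) plus a ridge
    λ·tr(Σ)/p·I (default λ = 1e-6) guarding against singular covariances in
    small folds. The discriminant score of class c at x is

        δ_c(x) = xᵀ Σ⁻¹ μ_c − ½ μ_cᵀ Σ⁻¹ μ_c + log π_c

    and prediction is the argmax, ties broken by class-label order.
    When the pooled covariance is identically zero (each class a single
    point) the identity matrix is used, reducing LDA to nearest class mean.
    """

    _param_names = ("ridge",)

    def __init__(self, ridge: float = 1e-6):
        self.ridge = ridge

    def fit(self, X, y, classes=None) -> "LinearDiscriminant":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=object)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        present = sorted(set(y))
        if classes is None:
            classes = present
        else:
            classes = list(classes)
            missing = [c for c in classes if c not in present]
            if missing:
                raise ValueError(f"class {missing[0]!r} has no training rows")
        if len(classes) < 2:
            raise ValueError("LDA requires at least 2 classes")
        n, p = X.shape
        C = len(classes)
        means = np.empty((C, p))
        priors = np.empty(C)
        scatter = np.zeros((p, p))
        for i, c in enumerate(classes):
            Xi = X[y == c]
            means[i] = Xi.mean(axis=0)
            priors[i] = Xi.shape[0] / n
            if Xi.shape[0] > 1:
                d = Xi - means[i]
                scatter += d.T @ d
        if n - C > 0:
            sigma = scatter / (n - C)
        else:
            sigma = np.zeros((p, p))
        tr = float(np.trace(sigma))
        if tr > 0:
            sigma = sigma + (self.ridge * tr / p) * np.eye(p)
        else:
            sigma = np.eye(p)
        self.class_labels_ = list(classes)
        self.class_means_ = means
        self.pooled_covariance_ = sigma
        self.priors_ = priors
        # δ_c(x) = x·w_c + b_c
        W = np.linalg.solve(sigma, means.T)  # p × C
        self._weights = W
        self._biases = -0.5 * np.einsum("cp,pc->c", means, W) + np.log(priors)
        return self

    def decision_function(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self._weights.shape[0]:
            raise ValueError(
                f"feature count {X.shape[1]} does not match fit ({self._weights.shape[0]})"
            )
        return X @ self._weights + self._biases

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        idx = np.argmax(scores, axis=1)  # first max -> class-label order ties
        return np.array([self.class_labels_[i] for i in idx], dtype=object)


class KNearestNeighbors(_Estimator):
    """k-nearest-neighbour classifier (Euclidean, majority vote).

    Vote ties are broken by the smallest mean neighbour distance among the
    tied labels, then by label order.
    """

    _param_names = ("k",)

    def __init__(self, k: int = 5):
        self.k = k

    def fit(self, X, y, classes=None) -> "KNearestNeighbors":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=object)
        if not 1 <= self.k <= X.shape[0]:
            raise ValueError(f"k={self.k} must lie in [1, {X.shape[0]}]")
        self.train_X_ = X
        self.train_y_ = y
        return self

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        d2 = ((X[:, None, :] - self.train_X_[None, :, :]) ** 2).sum(axis=2)
        out = np.empty(X.shape[0], dtype=object)
        for i in range(X.shape[0]):
            order = np.argsort(d2[i], kind="stable")[: self.k]
            neigh_y = self.train_y_[order]
            neigh_d = np.sqrt(d2[i][order])
            labels, counts = np.unique(neigh_y.astype(str), return_counts=True)
            top = counts.max()
            tied = [l for l, c in zip(labels, counts) if c == top]
            if len(tied) == 1:
                out[i] = tied[0]
            else:
                # smallest mean neighbour distance, then label order
                mean_d = {l: neigh_d[neigh_y.astype(str) == l].mean() for l in tied}
                out[i] = min(sorted(tied), key=lambda l: (mean_d[l], l))
        return out


# -- functional wrappers ----------------------------------------------------

def pca_fit(matrix, n_components: int) -> PrincipalComponents:
    return PrincipalComponents(n_components).fit(matrix)


def pca_transform(model: PrincipalComponents, matrix) -> np.ndarray:
    return model.transform(matrix)


def lda_fit(scores, labels, ridge: float = 1e-6) -> LinearDiscriminant:
    return LinearDiscriminant(ridge=ridge).fit(scores, labels)


def lda_predict(model: LinearDiscriminant, scores) -> np.ndarray:
    return model.predict(scores)


def knn_predict(train_scores, train_labels, test_scores, k: int = 5) -> np.ndarray:
    return KNearestNeighbors(k=k).fit(train_scores, train_labels).predict(test_scores)
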