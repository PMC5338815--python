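"""Metric multidimensional scaling with a Nystrom out-of-sample extension.

Classical (Torgerson) metric MDS converts an n x n distance matrix D into a
Gram (cross-product) matrix by double-centering the *squared* distances,

    B = -1/2 J D^(2) J,   J = I - 11^T / n,

and embeds the subjects with the top-M eigenpairs of B: subject i gets
coordinates e_im = sqrt(lambda_m) v_im.  A new point x with distances
d(x, x_i) to the training set is projected without refitting through the
centred kernel

    K(x, x_i) = -1/2 ( d^2(x, x_i) - rowmean_i - mean_j d^2(x, x_j) + grandmean )
    e_m(x)    = 1/sqrt(lambda_m) * sum_i v_im K(x, x_i),

the unique scaling for which projecting a training row reproduces that
subject's training coordinates exactly (Bengio-style spectral out-of-sample
extension).  Centering the raw (unsquared) distances instead is available via
``center_squared=False`` for compatibility; it stays internally
self-consistent but no longer reproduces Euclidean geometry, so it is not
the default.

Negative eigenvalues (a non-Euclidean distance matrix) are never used for
coordinates; they are retained on the model for inspection.
"""
from __future__ import annotations

import json

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["ClassicalMDS", "double_center", "fit_mds", "embed_new"]


def _validate_square(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=np.float64)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError(f"expected a square distance matrix, got shape {D.shape}")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if (D < 0).any():
        raise ValueError("distance matrix must be non-negative")
    return D


def double_center(D: np.ndarray, squared: bool = True) -> np.ndarray:
    """Double-centered cross-product matrix -1/2 J D^(2) J (rows/cols sum to 0)."""
    D = _validate_square(D)
    M = D**2 if squared else D
    n = D.shape[0]
    row = M.mean(axis=1, keepdims=True)
    grand = M.mean()
    return -0.5 * (M - row - row.T + grand)


class ClassicalMDS(TransformerMixin, BaseEstimator):
    """Classical metric MDS on a precomputed distance matrix.

    Parameters
    ----------
    n_components : int, default 3
        Embedding dimension M; fit fails if fewer than M eigenvalues of the
        centered matrix are strictly positive.
    center_squared : bool, default True
        Center squared distances (classical MDS).  False centers the raw
        distances (compatibility mode; Euclidean geometry is not recovered).

    Attributes
    ----------
    embedding_ : (n, M) training coordinates, column m = sqrt(lambda_m) v_m.
    eigenvalues_ : (M,) retained eigenvalues, descending, all > 0.
    eigenvectors_ : (n, M) unit-norm eigenvectors.
    all_eigenvalues_ : full spectrum, descending (negatives reported, unused).
    row_means_ : (n,) row means of the (squared) distance matrix.
    grand_mean_ : scalar grand mean of the (squared) distance matrix.
    """

    def __init__(self, n_components: int = 3, center_squared: bool = True):
        self.n_components = n_components
        self.center_squared = center_squared

    def fit(self, X, y=None):
        D = _validate_square(np.asarray(X))
        n = D.shape[0]
        M = int(self.n_components)
        if n <= M:
            raise ValueError(
                f"need at least n_components + 1 = {M + 1} subjects, got {n}"
            )
        S = D**2 if self.center_squared else D
        B = double_center(D, squared=self.center_squared)
        B = 0.5 * (B + B.T)  # enforce exact symmetry for eigh
        evals, evecs = np.linalg.eigh(B)
        order = np.argsort(evals)[::-1]  # descending; ties keep index order
        evals, evecs = evals[order], evecs[:, order]
        if (evals[:M] <= 0).any():
            n_pos = int((evals > 0).sum())
            raise ValueError(
                f"only {n_pos} positive eigenvalues; reduce n_components from {M} "
                "or repair the distance matrix"
            )
        vecs = evecs[:, :M].copy()
        # deterministic sign: largest-|.| entry of each eigenvector positive
        for m in range(M):
            i = int(np.argmax(np.abs(vecs[:, m])))
            if vecs[i, m] < 0:
                vecs[:, m] = -vecs[:, m]
        self.n_features_in_ = n
        self.all_eigenvalues_ = evals
        self.eigenvalues_ = evals[:M].copy()
        self.eigenvectors_ = vecs
        self.embedding_ = vecs * np.sqrt(self.eigenvalues_)
        self.row_means_ = S.mean(axis=1)
        self.grand_mean_ = float(S.mean())
        self.squared_dists_ = S
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X, y).embedding_

    def transform(self, X):
        """Nystrom out-of-sample projection.

        X : (m, n) distances from m new points to the n training points (a
        1-D array is treated as a single point).
        """
        check_is_fitted(self, "embedding_")
        X = np.asarray(X, dtype=np.float64)
        single = X.ndim == 1
        if single:
            X = X[np.newaxis, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected distances to {self.n_features_in_} training points, "
                f"got {X.shape[1]}"
            )
        if (X < 0).any():
            raise ValueError("distances must be non-negative")
        S = X**2 if self.center_squared else X
        K = -0.5 * (
            S - self.row_means_[np.newaxis, :]
            - S.mean(axis=1, keepdims=True)
            + self.grand_mean_
        )
        out = K @ self.eigenvectors_ / np.sqrt(self.eigenvalues_)
        return out[0] if single else out

    def to_json(self, subject_ids=None) -> str:
        check_is_fitted(self, "embedding_")
        return json.dumps(
            {
                "subject_ids": list(subject_ids) if subject_ids is not None else None,
                "n_components": int(self.n_components),
                "center_squared": bool(self.center_squared),
                "eigenvalues": self.eigenvalues_.tolist(),
                "all_eigenvalues": self.all_eigenvalues_.tolist(),
                "eigenvectors": self.eigenvectors_.tolist(),
                "row_means": self.row_means_.tolist(),
                "grand_mean": self.grand_mean_,
                "embedding": self.embedding_.tolist(),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ClassicalMDS":
        d = json.loads(text)
        model = cls(d["n_components"], d["center_squared"])
        model.eigenvalues_ = np.asarray(d["eigenvalues"])
        model.all_eigenvalues_ = np.asarray(d["all_eigenvalues"])
        model.eigenvectors_ = np.asarray(d["eigenvectors"])
        model.row_means_ = np.asarray(d["row_means"])
        model.grand_mean_ = float(d["grand_mean"])
        model.embedding_ = np.asarray(d["embedding"])
        model.n_features_in_ = model.eigenvectors_.shape[0]
        return model


def fit_mds(D, n_components: int = 3, center_squared: bool = True) -> ClassicalMDS:
    """Functional wrapper over :class:`ClassicalMDS`."""
    values = D.values if hasattr(D, "values") else D
    return ClassicalMDS(n_components, center_squared).fit(values)


def embed_new(model: ClassicalMDS, dists_to_train) -> np.ndarray:
    """Project new point(s) from their distances to the training set."""
    return model.transform(dists_to_train)
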