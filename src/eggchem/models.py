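"""Multivariate models: PCA (exploration), PLS-DA and LS-SVM (classification).

All three are implemented from their defining linear algebra: PCA by
singular value decomposition of the centered matrix, PLS-DA by the
single-response NIPALS recursion, and LS-SVM by solving its
Karush-Kuhn-Tucker linear system.  Everything is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import LinAlgError, solve
from scipy.spatial.distance import cdist

from .panel import CLASS_CODES, NEGATIVE_CLASS, POSITIVE_CLASS
from .preprocess import fit_column_scaler

SCHEMA_VERSION = 1


def encode_labels(labels) -> np.ndarray:
    """Map class-name labels to the +/-1 coding (positive = free-range)."""
    labels = np.asarray(labels)
    if labels.dtype.kind in "if":
        codes = labels.astype(int)
        if not set(np.unique(codes)) <= {-1, 1}:
            raise ValueError("numeric labels must be +/-1")
        return codes
    unknown = set(labels) - set(CLASS_CODES)
    if unknown:
        raise ValueError(f"unknown class labels: {sorted(unknown)}")
    return np.asarray([CLASS_CODES[l] for l in labels], dtype=int)


def decode_labels(codes) -> np.ndarray:
    names = {1: POSITIVE_CLASS, -1: NEGATIVE_CLASS}
    return np.asarray([names[int(c)] for c in np.asarray(codes)], dtype=object)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAModel:
    """Principal components of a centered data matrix.

    ``explained_variance_ratio`` covers all ``min(n - 1, p)`` components
    (summing to 1); ``loadings``/``scores`` keep only the leading
    ``n_components``.
    """

    mean: np.ndarray
    loadings: np.ndarray  # p x k, orthonormal columns
    scores: np.ndarray  # n x k
    explained_variance_ratio: np.ndarray
    n_components: int

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) @ self.loadings


def pca_fit(X: np.ndarray, n_components: int | None = None) -> PCAModel:
    """Fit PCA by SVD; data are mean-centered internally."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    m = min(n - 1, p)
    if m < 1:
        raise ValueError("need at least 2 samples and 1 variable")
    if n_components is None:
        n_components = m
    if not 1 <= n_components <= m:
        raise ValueError(f"n_components must be in [1, {m}]")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    s = s[:m]
    total = float(np.sum(s**2))
    if total == 0:
        raise ValueError("zero-variance input: all samples identical")
    return PCAModel(
        mean=mean,
        loadings=Vt[:n_components].T,
        scores=(U[:, :m] * s)[:, :n_components],
        explained_variance_ratio=s**2 / total,
        n_components=n_components,
    )


# ---------------------------------------------------------------------------
# PLS-DA (single coded response, NIPALS)
# ---------------------------------------------------------------------------


@dataclass
class PLSDAModel:
    """Fitted partial least squares discriminant model (binary, PLS1).

    The regression operates on the +/-1 coded response; the decision
    threshold is 0 and a predicted score of exactly 0 goes to the
    positive class.
    """

    n_components: int
    x_mean: np.ndarray
    y_mean: float
    x_weights: np.ndarray  # p x k
    x_loadings: np.ndarray  # p x k
    y_loadings: np.ndarray  # k
    x_scores: np.ndarray  # n x k (training scores)
    coef: np.ndarray  # p
    intercept: float
    class_codes: dict = field(default_factory=lambda: dict(CLASS_CODES))

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "family": "plsda",
            "n_components": self.n_components,
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "x_weights": self.x_weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "class_codes": dict(self.class_codes),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PLSDAModel":
        return cls(
            n_components=int(d["n_components"]),
            x_mean=np.asarray(d["x_mean"], dtype=float),
            y_mean=float(d["y_mean"]),
            x_weights=np.asarray(d["x_weights"], dtype=float),
            x_loadings=np.asarray(d["x_loadings"], dtype=float),
            y_loadings=np.asarray(d["y_loadings"], dtype=float),
            x_scores=np.empty((0, int(d["n_components"]))),
            coef=np.asarray(d["coef"], dtype=float),
            intercept=float(d["intercept"]),
            class_codes=dict(d["class_codes"]),
        )


def plsda_fit(X: np.ndarray, y, n_components: int) -> PLSDAModel:
    """Fit PLS1 on (X, coded y) with classical X-deflation.

    Raises if ``n_components`` exceeds the rank of the centered training
    matrix (no silent truncation) or if a class is missing.
    """
    X = np.asarray(X, dtype=float)
    y = encode_labels(y).astype(float)
    if len(set(y)) < 2:
        raise ValueError("training data must contain both classes")
    if n_components < 1:
        raise ValueError("need at least one latent variable")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    rank = int(np.linalg.matrix_rank(X - x_mean))
    if n_components > rank:
        raise ValueError(
            f"n_components={n_components} exceeds training matrix rank {rank}"
        )

    Xc = X - x_mean
    yc = y - y_mean
    n, p = X.shape
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    T = np.zeros((n, n_components))
    for a in range(n_components):
        w = Xc.T @ yc
        norm = np.linalg.norm(w)
        if norm == 0:
            raise ValueError(
                f"response is orthogonal to the deflated X at component {a + 1}"
            )
        w /= norm
        t = Xc @ w
        tt = float(t @ t)
        P[:, a] = Xc.T @ t / tt
        q[a] = float(yc @ t) / tt
        W[:, a] = w
        T[:, a] = t
        Xc = Xc - np.outer(t, P[:, a])

    coef = W @ np.linalg.solve(P.T @ W, q)
    intercept = y_mean - float(x_mean @ coef)
    return PLSDAModel(
        n_components=n_components,
        x_mean=x_mean,
        y_mean=y_mean,
        x_weights=W,
        x_loadings=P,
        y_loadings=q,
        x_scores=T,
        coef=coef,
        intercept=intercept,
    )


def plsda_predict(model: PLSDAModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Continuous scores and +/-1 classes (score >= 0 -> positive)."""
    X = np.asarray(X, dtype=float)
    score = X @ model.coef + model.intercept
    classes = np.where(score >= 0, 1, -1)
    return score, classes


# ---------------------------------------------------------------------------
# LS-SVM with RBF kernel
# ---------------------------------------------------------------------------


def rbf_kernel(A: np.ndarray, B: np.ndarray, sigma2: float) -> np.ndarray:
    """K(u, v) = exp(-||u - v||^2 / sigma2).

    The width parameter is the *squared* kernel scale; the package treats
    a tuned magnitude like 700 as sigma^2.
    """
    if not sigma2 > 0:
        raise ValueError("sigma2 must be > 0")
    return np.exp(-cdist(A, B, metric="sqeuclidean") / sigma2)


@dataclass
class LSSVMModel:
    """Fitted least-squares SVM: dual coefficients, bias and kernel state."""

    sigma2: float
    gamma: float
    alpha: np.ndarray
    bias: float
    X_train: np.ndarray
    class_codes: dict = field(default_factory=lambda: dict(CLASS_CODES))

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "family": "lssvm",
            "sigma2": self.sigma2,
            "gamma": self.gamma,
            "alpha": self.alpha.tolist(),
            "bias": self.bias,
            "X_train": self.X_train.tolist(),
            "class_codes": dict(self.class_codes),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LSSVMModel":
        return cls(
            sigma2=float(d["sigma2"]),
            gamma=float(d["gamma"]),
            alpha=np.asarray(d["alpha"], dtype=float),
            bias=float(d["bias"]),
            X_train=np.asarray(d["X_train"], dtype=float),
            class_codes=dict(d["class_codes"]),
        )


def lssvm_fit(
    X: np.ndarray, y, sigma2: float, gamma: float, residual_tol: float = 1e-8
) -> LSSVMModel:
    """Solve the LS-SVM KKT system  [[0, 1^T], [1, K + I/gamma]] [b; a] = [0; y].

    The solution must satisfy the system to ``residual_tol`` (relative to
    the right-hand-side norm); otherwise the system is reported as
    ill-conditioned with its condition number.
    """
    X = np.asarray(X, dtype=float)
    y = encode_labels(y).astype(float)
    if len(set(y)) < 2:
        raise ValueError("training data must contain both classes")
    if not sigma2 > 0 or not gamma > 0:
        raise ValueError("sigma2 and gamma must be > 0")
    n = len(X)
    K = rbf_kernel(X, X, sigma2)
    M = np.zeros((n + 1, n + 1))
    M[0, 1:] = 1.0
    M[1:, 0] = 1.0
    M[1:, 1:] = K + np.eye(n) / gamma
    rhs = np.concatenate(([0.0], y))
    try:
        sol = solve(M, rhs, assume_a="sym")
    except LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular KKT system (cond={np.linalg.cond(M):.3e}); "
            "duplicate training points at extreme gamma?"
        ) from exc
    residual = np.linalg.norm(M @ sol - rhs) / max(np.linalg.norm(rhs), 1.0)
    if residual > residual_tol:
        raise np.linalg.LinAlgError(
            f"KKT solution residual {residual:.3e} exceeds {residual_tol:.1e} "
            f"(cond={np.linalg.cond(M):.3e})"
        )
    return LSSVMModel(
        sigma2=sigma2, gamma=gamma, alpha=sol[1:], bias=float(sol[0]), X_train=X
    )


def lssvm_predict(model: LSSVMModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Decision values f(x) = sum_i a_i K(x, x_i) + b and +/-1 classes."""
    X = np.asarray(X, dtype=float)
    f = rbf_kernel(X, model.X_train, model.sigma2) @ model.alpha + model.bias
    classes = np.where(f >= 0, 1, -1)
    return f, classes


# ---------------------------------------------------------------------------
# Classifier front-ends with internal (leak-free) autoscaling
# ---------------------------------------------------------------------------


class _ScaledClassifier:
    """fit/predict wrapper that autoscales on the training data only."""

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self.center_, self.scale_ = fit_column_scaler(X)
        self._fit_scaled((X - self.center_) / self.scale_, y)
        return self

    def predict(self, X) -> np.ndarray:
        return self.decision_function(X)[1]

    def decision_function(self, X):
        X = (np.asarray(X, dtype=float) - self.center_) / self.scale_
        return self._predict_scaled(X)


class PLSDAClassifier(_ScaledClassifier):
    """PLS-DA with a fixed number of latent variables."""

    def __init__(self, n_components: int = 4):
        self.n_components = n_components

    def get_params(self) -> dict:
        return {"n_components": self.n_components}

    def _fit_scaled(self, X, y):
        self.model_ = plsda_fit(X, y, self.n_components)

    def _predict_scaled(self, X):
        return plsda_predict(self.model_, X)


class LSSVMClassifier(_ScaledClassifier):
    """LS-SVM with RBF kernel, parameterized by (sigma2, gamma)."""

    def __init__(self, sigma2: float = 700.0, gamma: float = 5.0):
        self.sigma2 = sigma2
        self.gamma = gamma

    def get_params(self) -> dict:
        return {"sigma2": self.sigma2, "gamma": self.gamma}

    def _fit_scaled(self, X, y):
        self.model_ = lssvm_fit(X, y, self.sigma2, self.gamma)

    def _predict_scaled(self, X):
        return lssvm_predict(self.model_, X)


MODEL_FAMILIES = {"plsda": PLSDAClassifier, "lssvm": LSSVMClassifier}
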