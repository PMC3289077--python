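"""Hybrid SVM-KNN classifier.

An RBF-kernel SVM provides the decision function f(x) = sum_i a_i K(x, x_i) + b.
Samples whose functional margin |f(x)| exceeds a threshold T are classified
by the SVM sign; the rest fall inside the uncertainty band and are decided
by a class-weighted k-nearest-neighbor vote among the support vectors,
measured in the kernel-induced feature space.

The dual optimization is delegated to scikit-learn's SVC; the extracted
support vectors, signed coefficients and bias reproduce its decision
function through :func:`decision_value`.  Kernel, distances, routing and
the vote are implemented here.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateModelError, DegenerateTrainingError
from .features import FeatureTable

logger = logging.getLogger(__name__)

DEFAULT_C = 1.0
DEFAULT_GAMMA = 0.0625
DEFAULT_T = 1.0
DEFAULT_K = 5

MODEL_FORMAT_VERSION = 1


def rbf_kernel(x: np.ndarray, y: np.ndarray, gamma: float) -> float:
    """exp(-gamma * ||x - y||^2); symmetric, in (0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return float(np.exp(-gamma * np.sum((x - y) ** 2)))


def kernel_distance(x: np.ndarray, y: np.ndarray, gamma: float) -> float:
    """Distance between the RBF feature-space images of x and y.

    For a normalized kernel (K(x,x)=1) this is sqrt(2 - 2 K(x,y)); zero iff
    x = y, approaching sqrt(2) as the points separate.
    """
    return math.sqrt(max(2.0 - 2.0 * rbf_kernel(x, y, gamma), 0.0))


@dataclass
class SvmKnnModel:
    """Trained hybrid model: SVM pieces plus the routing/vote parameters."""

    support_vectors: np.ndarray  # (n_sv, dim)
    sv_labels: np.ndarray  # (n_sv,) in {+1, -1}
    alphas: np.ndarray  # signed dual coefficients, sign(a_i) = y_i
    bias: float
    gamma: float
    C: float = DEFAULT_C
    T: float = DEFAULT_T
    k: int = DEFAULT_K
    C1: float = 1.0
    C2: float = 1.0
    knn_pool: str = "support_vectors"  # or "training"
    training_points: np.ndarray | None = None
    training_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.support_vectors = np.asarray(self.support_vectors, dtype=float)
        self.sv_labels = np.asarray(self.sv_labels, dtype=int)
        self.alphas = np.asarray(self.alphas, dtype=float)
        if len(self.support_vectors) != len(self.alphas) or len(self.alphas) != len(self.sv_labels):
            raise ValueError("support vectors, labels and alphas must align")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.T < 0:
            raise ValueError("T must be non-negative")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.C1 <= 0 or self.C2 <= 0:
            raise ValueError("vote weights must be positive")

    @property
    def dim(self) -> int:
        return self.support_vectors.shape[1] if self.support_vectors.size else 0


def decision_value(m: SvmKnnModel, x: np.ndarray) -> float:
    """f(x) = sum_i a_i K(x, x_i) + b."""
    x = np.asarray(x, dtype=float)
    if len(m.support_vectors) == 0:
        return m.bias  # empty sum
    diffs = m.support_vectors - x[None, :]
    k = np.exp(-m.gamma * np.sum(diffs * diffs, axis=1))
    return float(m.alphas @ k + m.bias)


def decision_values(m: SvmKnnModel, X: np.ndarray) -> np.ndarray:
    """Vectorized :func:`decision_value` over rows of X."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if len(m.support_vectors) == 0:
        raise DegenerateModelError("model has no support vectors")
    sq = (
        np.sum(X * X, axis=1)[:, None]
        + np.sum(m.support_vectors**2, axis=1)[None, :]
        - 2.0 * X @ m.support_vectors.T
    )
    K = np.exp(-m.gamma * np.clip(sq, 0.0, None))
    return K @ m.alphas + m.bias


def train(
    features: FeatureTable | tuple[np.ndarray, np.ndarray],
    C: float = DEFAULT_C,
    gamma: float = DEFAULT_GAMMA,
    T: float = DEFAULT_T,
    k: int = DEFAULT_K,
    C1: float | None = None,
    C2: float | None = None,
    class_weight: dict | None = None,
    knn_pool: str = "support_vectors",
) -> SvmKnnModel:
    """Train the hybrid model (SVM training is the standard soft-margin dual).

    Vote weights default to C1 = 1 and C2 = N-/N+ of the training set,
    balancing the class-size difference in the uncertainty-band vote.
    """
    from sklearn.svm import SVC

    if isinstance(features, FeatureTable):
        X, y01 = features.X, features.labels
    else:
        X, y01 = features
        X = np.asarray(X, dtype=float)
        y01 = np.asarray(y01, dtype=int)
    classes = np.unique(y01)
    if len(classes) < 2:
        raise DegenerateTrainingError(f"training data has a single class: {classes}")

    y = np.where(y01 == 1, 1, -1)
    n_pos = int((y == 1).sum())
    n_neg = int((y == -1).sum())
    if C1 is None:
        C1 = 1.0
    if C2 is None:
        C2 = n_neg / n_pos

    svc = SVC(C=C, kernel="rbf", gamma=gamma, class_weight=class_weight)
    svc.fit(X, y)
    # classes_ is [-1, 1]; dual_coef_ holds y_i * alpha_i for the positive class side
    model = SvmKnnModel(
        support_vectors=svc.support_vectors_.copy(),
        sv_labels=y[svc.support_],
        alphas=svc.dual_coef_[0].copy(),
        bias=float(svc.intercept_[0]),
        gamma=gamma,
        C=C,
        T=T,
        k=k,
        C1=C1,
        C2=C2,
        knn_pool=knn_pool,
        training_points=X.copy() if knn_pool == "training" else None,
        training_labels=y.copy() if knn_pool == "training" else None,
    )
    return model


def _knn_vote(m: SvmKnnModel, x: np.ndarray, fx: float) -> int:
    if m.knn_pool == "training" and m.training_points is not None:
        pool, pool_y = m.training_points, m.training_labels
    else:
        pool, pool_y = m.support_vectors, m.sv_labels
    k = m.k
    if k > len(pool):
        logger.warning("k=%d exceeds pool size %d: clamped", k, len(pool))
        k = len(pool)
    # kernel-induced distance is monotone in ||x - p||, so squared Euclidean
    # distances give the identical neighbor ranking
    sq = np.sum((pool - x[None, :]) ** 2, axis=1)
    nearest = np.argsort(sq, kind="stable")[:k]
    votes_pos = m.C1 * float(np.sum(pool_y[nearest] == 1))
    votes_neg = m.C2 * float(np.sum(pool_y[nearest] == -1))
    if votes_pos > votes_neg:
        return 1
    if votes_neg > votes_pos:
        return 0
    return int(fx > 0)  # tie -> SVM sign


def predict_one(m: SvmKnnModel, x: np.ndarray) -> tuple[int, str]:
    """Class in {0,1} and routing flag ('svm' or 'knn') for one sample.

    |f(x)| > T trusts the SVM sign; otherwise the k nearest support vectors
    (kernel-space distance) cast a C1/C2-weighted vote, ties falling back
    to the SVM sign.
    """
    x = np.asarray(x, dtype=float)
    fx = decision_value(m, x)
    if abs(fx) > m.T:
        return int(fx > 0), "svm"
    return _knn_vote(m, x, fx), "knn"


def predict(m: SvmKnnModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Classes and routing flags for every row of X."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    fx = decision_values(m, X)
    classes = np.empty(len(X), dtype=int)
    routing = np.empty(len(X), dtype=object)
    svm_mask = np.abs(fx) > m.T
    classes[svm_mask] = (fx[svm_mask] > 0).astype(int)
    routing[svm_mask] = "svm"
    for i in np.nonzero(~svm_mask)[0]:
        classes[i] = _knn_vote(m, X[i], fx[i])
        routing[i] = "knn"
    return classes, routing


def save_model(m: SvmKnnModel, path) -> None:
    """Serialize to a self-describing JSON archive."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "kind": "spasite-svmknn",
        "support_vectors": m.support_vectors.tolist(),
        "sv_labels": m.sv_labels.tolist(),
        "alphas": m.alphas.tolist(),
        "bias": m.bias,
        "gamma": m.gamma,
        "C": m.C,
        "T": m.T,
        "k": m.k,
        "C1": m.C1,
        "C2": m.C2,
        "knn_pool": m.knn_pool,
        "training_points": None if m.training_points is None else m.training_points.tolist(),
        "training_labels": None if m.training_labels is None else m.training_labels.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> SvmKnnModel:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("kind") != "spasite-svmknn":
        raise ValueError(f"{path}: not a spasite model archive")
    tp = payload["training_points"]
    tl = payload["training_labels"]
    return SvmKnnModel(
        support_vectors=np.asarray(payload["support_vectors"]),
        sv_labels=np.asarray(payload["sv_labels"]),
        alphas=np.asarray(payload["alphas"]),
        bias=payload["bias"],
        gamma=payload["gamma"],
        C=payload["C"],
        T=payload["T"],
        k=payload["k"],
        C1=payload["C1"],
        C2=payload["C2"],
        knn_pool=payload["knn_pool"],
        training_points=None if tp is None else np.asarray(tp),
        training_labels=None if tl is None else np.asarray(tl),
    )
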