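"""Soft-margin RBF-kernel SVM: training, prediction, tenfold grid search.

The kernel is K(x, y) = exp(−‖x−y‖²/(2g²)).  Solvers that parameterize the
RBF as exp(−γ‖x−y‖²) must receive γ = 1/(2g²): the published optimum
(c, g) = (10, 3.1623) therefore corresponds to γ = 0.05.  Labels are
+1 (normal) and −1 (suspicious); a decision value of exactly 0 maps to +1.

The dual problem is solved by scikit-learn's SVC; the fitted model is then
carried as an explicit (support vectors, dual coefficients, bias) triple so
the decision function is computed in closed form here — a serialized and
reloaded model is bit-identical in its predictions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .features import FEATURE_NAMES, NormalizationParams

DEFAULT_C = 10.0
DEFAULT_G = 3.1623
DEFAULT_FOLDS = 10
#: Default grid: log10 c ∈ [−2, 3], log10 g ∈ [−2, 2], step 0.25 — covers
#: the published optimum at (log10 c, log10 g) = (1, 0.5).
DEFAULT_LOG10_C = (-2.0, 3.0)
DEFAULT_LOG10_G = (-2.0, 2.0)
DEFAULT_GRID_STEP = 0.25


def g_to_gamma(g: float) -> float:
    """Map the kernel width g of K = exp(−‖x−y‖²/(2g²)) to solver γ."""
    return 1.0 / (2.0 * g * g)


def rbf_kernel(a: np.ndarray, b: np.ndarray, g: float) -> np.ndarray:
    """K(a_i, b_j) = exp(−‖a_i−b_j‖² / (2g²))."""
    return np.exp(-cdist(np.atleast_2d(a), np.atleast_2d(b), "sqeuclidean") / (2.0 * g * g))


@dataclass
class TrainedModel:
    support_vectors: np.ndarray   # (n_sv, n_features), normalized scale
    dual_coef: np.ndarray         # (n_sv,), y_i α_i
    bias: float
    c: float
    g: float
    normalization: NormalizationParams | None = None
    cv_accuracy: float | None = None
    fold_seed: int | None = None


def _validate_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int).ravel()
    if X.shape[0] != y.size:
        raise ValueError("feature matrix and labels disagree in length")
    if not set(np.unique(y)) <= {-1, 1}:
        raise ValueError("labels must be +1 (normal) or −1 (suspicious)")
    if np.unique(y).size < 2:
        raise ValueError("training needs both classes present")
    return X, y


def train(
    X: np.ndarray,
    y: np.ndarray,
    c: float = DEFAULT_C,
    g: float = DEFAULT_G,
    normalization: NormalizationParams | None = None,
) -> TrainedModel:
    """Solve the soft-margin dual on normalized features.

    ``X`` is expected to be min–max normalized already; pass the fitted
    ``normalization`` so it travels with the model for later raw inputs.
    """
    X, y = _validate_xy(X, y)
    svc = SVC(C=c, kernel="rbf", gamma=g_to_gamma(g))
    svc.fit(X, y)
    return TrainedModel(
        support_vectors=svc.support_vectors_.copy(),
        dual_coef=svc.dual_coef_.ravel().copy(),
        bias=float(svc.intercept_[0]),
        c=c,
        g=g,
        normalization=normalization,
    )


def decision_function(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Σ_i (y_i α_i) K(x_i, x) + b, evaluated from the stored dual solution."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.support_vectors.shape[1]:
        raise ValueError(
            f"expected {model.support_vectors.shape[1]}-dimensional features, got {X.shape[1]}"
        )
    K = rbf_kernel(X, model.support_vectors, model.g)
    return K @ model.dual_coef + model.bias


def predict(model: TrainedModel, X: np.ndarray, prenormalized: bool = True) -> np.ndarray:
    """Labels in {+1, −1}; decision value exactly 0 maps to +1 (normal).

    With ``prenormalized=False`` the model's stored min–max parameters are
    applied first.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not prenormalized:
        if model.normalization is None:
            raise ValueError("model carries no normalization parameters")
        X = model.normalization.transform(X)
    return np.where(decision_function(model, X) >= 0, 1, -1)


@dataclass
class GridSearchResult:
    log10_c: np.ndarray           # grid axis values
    log10_g: np.ndarray
    accuracy: np.ndarray          # (len(log10_c), len(log10_g)) CV accuracies
    best_c: float
    best_g: float
    best_accuracy: float
    folds: int
    seed: int


def _canonical_order(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    # Sort samples lexicographically so fold assignment depends only on the
    # data multiset, never on input order.
    keys = tuple(X[:, j] for j in range(X.shape[1] - 1, -1, -1)) + (y,)
    return np.lexsort(keys)


def cv_accuracy(X: np.ndarray, y: np.ndarray, c: float, g: float, folds: int, seed: int) -> float:
    """Stratified k-fold CV accuracy (pooled over folds) at one (c, g)."""
    X, y = _validate_xy(X, y)
    order = _canonical_order(X, y)
    X, y = X[order], y[order]
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    correct = 0
    for train_idx, test_idx in skf.split(X, y):
        model = train(X[train_idx], y[train_idx], c, g)
        correct += int(np.sum(predict(model, X[test_idx]) == y[test_idx]))
    return correct / y.size


def grid_search(
    X: np.ndarray,
    y: np.ndarray,
    folds: int = DEFAULT_FOLDS,
    log10_c_range: tuple[float, float] = DEFAULT_LOG10_C,
    log10_g_range: tuple[float, float] = DEFAULT_LOG10_G,
    step: float = DEFAULT_GRID_STEP,
    seed: int = 0,
) -> GridSearchResult:
    """Tenfold-CV grid search over log-spaced (c, g).

    Ties in CV accuracy break toward smaller c, then smaller g (the grid is
    scanned in ascending order and only strict improvements replace the
    incumbent).
    """
    X, y = _validate_xy(X, y)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"each class needs at least {folds} samples for {folds}-fold CV "
            f"(smallest class has {counts.min()})"
        )
    lc = np.arange(log10_c_range[0], log10_c_range[1] + step / 2, step)
    lg = np.arange(log10_g_range[0], log10_g_range[1] + step / 2, step)
    acc = np.empty((lc.size, lg.size))
    best = (-1.0, None, None)
    for i, log_c in enumerate(lc):
        for j, log_g in enumerate(lg):
            a = cv_accuracy(X, y, 10.0**log_c, 10.0**log_g, folds, seed)
            acc[i, j] = a
            if a > best[0]:
                best = (a, 10.0**log_c, 10.0**log_g)
    return GridSearchResult(
        log10_c=lc, log10_g=lg, accuracy=acc,
        best_c=float(best[1]), best_g=float(best[2]), best_accuracy=float(best[0]),
        folds=folds, seed=seed,
    )


# --- model serialization (JSON, documented in README) ----------------------

def save_model(model: TrainedModel, path: str | Path) -> None:
    """Write a model to a JSON file (arrays stored as full-precision lists)."""
    payload = {
        "format": "cytoblock-svm-v1",
        "support_vectors": model.support_vectors.tolist(),
        "dual_coef": model.dual_coef.tolist(),
        "bias": model.bias,
        "c": model.c,
        "g": model.g,
        "cv_accuracy": model.cv_accuracy,
        "fold_seed": model.fold_seed,
        "normalization": None
        if model.normalization is None
        else {
            "minimum": model.normalization.minimum.tolist(),
            "maximum": model.normalization.maximum.tolist(),
            "feature_names": list(model.normalization.feature_names),
        },
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> TrainedModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "cytoblock-svm-v1":
        raise ValueError(f"{path} is not a cytoblock SVM model file")
    norm = payload["normalization"]
    normalization = (
        None
        if norm is None
        else NormalizationParams(
            minimum=np.array(norm["minimum"]),
            maximum=np.array(norm["maximum"]),
            feature_names=tuple(norm["feature_names"]),
        )
    )
    return TrainedModel(
        support_vectors=np.array(payload["support_vectors"]),
        dual_coef=np.array(payload["dual_coef"]),
        bias=float(payload["bias"]),
        c=float(payload["c"]),
        g=float(payload["g"]),
        normalization=normalization,
        cv_accuracy=payload.get("cv_accuracy"),
        fold_seed=payload.get("fold_seed"),
    )
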