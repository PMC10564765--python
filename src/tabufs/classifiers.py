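"""The three classifiers the wrapper scores subsets with, behind one contract.

The search evaluates thousands of feature subsets, each requiring a model
fit on the training cases restricted to that subset, so fit speed dominates
the wrapper's runtime.  Discriminant analysis (``"da"``) is therefore
implemented closed-form with NumPy — class means plus pooled covariance,
empirical priors — from sufficient statistics computed once per dataset, so
a subset fit only touches a |S| x |S| submatrix; its predictions are
cross-checked against scikit-learn's LDA in the test suite.  Logistic
regression (``"lr"``) and the linear SVM (``"svm"``) wrap scikit-learn's
solvers (L2 penalty, C=1, tol=1e-4, max_iter=1000); any solver meeting the
determinism contract is acceptable, since the wrapper never inspects solver
internals.

Additional classifiers can be plugged in via :func:`register_classifier`;
a fit function receives the full :class:`~tabufs.data_io.Dataset` and the
tuple of selected column indices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING, Callable, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC

if TYPE_CHECKING:  # pragma: no cover
    from .data_io import Dataset
    from .objective import FeatureSubset


@dataclass
class ClassifierModel:
    """A fitted binary classifier bound to the feature subset it was trained on."""

    kind: str
    backend: object  # fitted estimator or closed-form parameter bundle
    selected: tuple[int, ...]
    m: int  # width of the universe the subset indexes into


# registry: kind -> (fit_fn(ds, members) -> backend, predict_fn(backend, Xs) -> y_hat)
_REGISTRY: dict[str, tuple[Callable, Callable]] = {}


def register_classifier(kind: str, fit_fn: Callable, predict_fn: Callable) -> None:
    """Register a classifier under ``kind``.

    ``fit_fn(ds, members)`` receives the dataset and the selected column
    indices and returns an opaque backend object; ``predict_fn(backend, X)``
    receives the subset-restricted float matrix and returns a 0/1 label
    vector.
    """
    _REGISTRY[kind] = (fit_fn, predict_fn)


def registered_kinds() -> list[str]:
    return sorted(_REGISTRY)


# ---------------------------------------------------------------------------
# discriminant analysis: linear, pooled covariance, empirical priors
# ---------------------------------------------------------------------------

_LDA_RIDGE = 1e-6


def _da_stats(ds: "Dataset"):
    """Per-dataset sufficient statistics for pooled-covariance LDA.

    Cached on the dataset object: class means and the pooled within-class
    scatter matrix, from which any column subset's fit is a submatrix
    extraction plus a small linear solve.
    """
    stats = getattr(ds, "_da_stats_cache", None)
    if stats is not None:
        return stats
    X = ds.features
    pos = ds.labels == 1
    X1, X0 = X[pos], X[~pos]
    n1, n0 = len(X1), len(X0)
    if n1 == 0 or n0 == 0:
        raise ValueError("training data must contain both classes")
    mu1 = X1.mean(axis=0)
    mu0 = X0.mean(axis=0)
    scatter = (X1.T @ X1 - n1 * np.outer(mu1, mu1)) + (X0.T @ X0 - n0 * np.outer(mu0, mu0))
    stats = (n0, n1, mu0, mu1, scatter, pos)
    ds._da_stats_cache = stats
    return stats


def _fit_da(ds: "Dataset", members: tuple[int, ...]):
    n0, n1, mu0, mu1, scatter, _ = _da_stats(ds)
    idx = np.asarray(members, dtype=int)
    cov = scatter[np.ix_(idx, idx)] / max(n0 + n1 - 2, 1)
    m0, m1 = mu0[idx], mu1[idx]
    diff = m1 - m0
    try:
        w = np.linalg.solve(cov, diff)
    except np.linalg.LinAlgError:
        warnings.warn(
            "singular within-class covariance; using diagonal-regularized estimate",
            stacklevel=2,
        )
        w = np.linalg.solve(cov + _LDA_RIDGE * np.eye(cov.shape[0]), diff)
    # decide 1 iff w.x - w.(mu0+mu1)/2 + log(pi1/pi0) > 0
    bias = -0.5 * w @ (m0 + m1) + np.log(n1 / n0)
    return w, bias


def _predict_da(backend, X: np.ndarray) -> np.ndarray:
    w, bias = backend
    return (X @ w + bias > 0.0).astype(int)


def resubstitution_rate_da(ds: "Dataset", members: Sequence[int]) -> float:
    """Training-set accuracy of a DA fit on ``ds[:, members]``, fast path.

    Identical in exact arithmetic to fit + predict + compare via the
    generic contract; it exists because the search calls this millions of
    times and the generic route spends most of its time in call overhead.
    """
    w, bias = _fit_da(ds, tuple(members))
    idx = np.asarray(members, dtype=int)
    pos = ds._da_stats_cache[5]
    pred_pos = ds.features[:, idx] @ w + bias > 0.0
    return np.count_nonzero(pred_pos == pos) / len(pos)


def resubstitution_rate_da_batch(
    ds: "Dataset", subsets: Sequence[Sequence[int]]
) -> np.ndarray:
    """Training-set accuracy of a DA fit for many equal-size subsets at once.

    All subsets must have the same cardinality.  Uses stacked linear solves
    and a single gathered scoring pass; falls back to the scalar path when
    any stacked covariance is singular.
    """
    n0, n1, mu0, mu1, scatter, pos = _da_stats(ds)
    idx = np.asarray(subsets, dtype=int)  # (c, k)
    cov = scatter[idx[:, :, None], idx[:, None, :]] / max(n0 + n1 - 2, 1)
    diff = (mu1 - mu0)[idx]
    try:
        w = np.linalg.solve(cov, diff[..., None])[..., 0]  # (c, k)
    except np.linalg.LinAlgError:
        return np.array([resubstitution_rate_da(ds, tuple(s)) for s in subsets])
    bias = -0.5 * np.einsum("ck,ck->c", w, (mu0 + mu1)[idx]) + np.log(n1 / n0)
    scores = np.einsum("nck,ck->nc", ds.features[:, idx], w) + bias  # (n, c)
    pred_pos = scores > 0.0
    return np.count_nonzero(pred_pos == pos[:, None], axis=0) / len(pos)


def _fit_lr(ds: "Dataset", members: tuple[int, ...]):
    est = LogisticRegression(C=1.0, tol=1e-4, max_iter=1000)  # L2 by default
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*converge.*")
        est.fit(ds.features[:, members], ds.labels)
    return est


def _fit_svm(ds: "Dataset", members: tuple[int, ...]):
    est = LinearSVC(C=1.0, penalty="l2", tol=1e-4, max_iter=1000)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*converge.*")
        est.fit(ds.features[:, members], ds.labels)
    return est


def _predict_sklearn(backend, X: np.ndarray) -> np.ndarray:
    return np.asarray(backend.predict(X), dtype=int)


register_classifier("da", _fit_da, _predict_da)
register_classifier("lr", _fit_lr, _predict_sklearn)
register_classifier("svm", _fit_svm, _predict_sklearn)


# ---------------------------------------------------------------------------
# the fit/predict contract
# ---------------------------------------------------------------------------

def fit(kind: str, ds: "Dataset", subset: "FeatureSubset | Sequence[int]") -> ClassifierModel:
    """Train classifier ``kind`` on ``ds`` restricted to ``subset``.

    Deterministic for DA; deterministic for LR/SVM at fixed solver settings.
    Requires a nonempty subset and both classes present in ``ds``.
    """
    members = tuple(getattr(subset, "members", subset))
    if len(members) == 0:
        raise ValueError("empty feature subset")
    if kind not in _REGISTRY:
        raise ValueError(f"unknown classifier kind {kind!r}; known: {registered_kinds()}")
    y = ds.labels
    if not 0 < y.sum() < len(y):
        raise ValueError("training data must contain both classes")
    fit_fn, _ = _REGISTRY[kind]
    backend = fit_fn(ds, members)
    return ClassifierModel(kind=kind, backend=backend, selected=members, m=ds.m)


def predict(model: ClassifierModel, ds: "Dataset") -> np.ndarray:
    """Predict 0/1 labels for ``ds`` using a fitted model.

    ``ds`` must present the same feature universe the model was trained
    against (same width ``m``); the model slices its own columns.
    """
    if ds.m != model.m:
        raise ValueError(
            f"feature universe mismatch: model trained on m={model.m}, got m={ds.m}"
        )
    _, predict_fn = _REGISTRY[model.kind]
    return predict_fn(model.backend, ds.features[:, model.selected])
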