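"""Nearest-shrunken-centroid (PAM-style) classification.

Class centroids are shrunk toward the overall centroid by soft-thresholding
the standardized centroid deviations

    d_ik = (xbar_ik - xbar_i) / (m_k * (s_i + s0)),   m_k = sqrt(1/n_k - 1/n)

with ``s_i`` the pooled within-class standard deviation of feature ``i`` and
``s0`` a fudge constant (default: median of the ``s_i``).  Soft threshold:
``d'_ik = sign(d_ik) * max(|d_ik| - delta, 0)``, and the shrunken centroid is
``xbar'_ik = xbar_i + m_k (s_i + s0) d'_ik``.  A sample is assigned to the
class minimizing the discriminant

    delta_k(x) = sum_i (x_i - xbar'_ik)^2 / (s_i + s0)^2 - 2 log pi_k

with class posteriors proportional to ``exp(-delta_k / 2)``.

The intended use here is two-class risk stratification of tumors on a single
continuous instability score (trained on histological-grade extremes), but
the implementation is general in features and classes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "NscModel",
    "RiskAssignment",
    "fit_nsc",
    "classify",
    "choose_delta_cv",
    "decision_threshold",
]


@dataclass
class NscModel:
    class_labels: list
    overall_centroid: np.ndarray      # (p,)
    class_centroids: np.ndarray       # (p, K)
    shrunken_centroids: np.ndarray    # (p, K)
    pooled_sd: np.ndarray             # (p,)
    s0: float
    m_k: np.ndarray                   # (K,)
    priors: np.ndarray                # (K,)
    delta: float
    d_raw: np.ndarray                 # (p, K) standardized deviations
    d_shrunk: np.ndarray              # (p, K)
    class_counts: np.ndarray          # (K,)
    cv_error_curve: dict | None = None

    @property
    def n_surviving_features(self) -> int:
        """Features with any nonzero shrunken deviation."""
        return int(np.sum(np.any(self.d_shrunk != 0, axis=1)))

    def to_json(self) -> str:
        doc = {
            "class_labels": [str(c) for c in self.class_labels],
            "overall_centroid": self.overall_centroid.tolist(),
            "class_centroids": self.class_centroids.tolist(),
            "shrunken_centroids": self.shrunken_centroids.tolist(),
            "pooled_sd": self.pooled_sd.tolist(),
            "s0": self.s0,
            "m_k": self.m_k.tolist(),
            "priors": self.priors.tolist(),
            "delta": self.delta,
            "class_counts": self.class_counts.tolist(),
        }
        return json.dumps(doc, indent=2)


@dataclass
class RiskAssignment:
    label: object
    posterior: np.ndarray
    discriminant: np.ndarray


def _as_feature_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]  # single feature, samples along axis 1
    if X.ndim != 2:
        raise ValueError("X must be a (features x samples) matrix")
    return X


def fit_nsc(X, labels, delta: float = 0.0, priors=None, s0: float | None = None) -> NscModel:
    """Fit the shrunken-centroid model.

    Parameters
    ----------
    X : (features, samples) matrix; a 1-d array is treated as one feature.
    labels : class label per sample (2 or more classes, each with >= 2
        samples so the pooled SD is defined).
    delta : shrinkage amount applied to the standardized deviations.
    priors : class priors; default = observed class frequencies.
    s0 : fudge constant added to each pooled SD; default = median(s_i).
    """
    X = _as_feature_matrix(X)
    labels = np.asarray(labels)
    p, n = X.shape
    if labels.shape != (n,):
        raise ValueError("labels length must equal the number of samples")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    if delta < 0:
        raise ValueError("delta must be >= 0")

    classes = [c for c in dict.fromkeys(labels.tolist())]  # first-appearance order
    classes = sorted(classes, key=str)
    K = len(classes)
    if K < 2:
        raise ValueError("need at least 2 classes")
    counts = np.array([int(np.sum(labels == c)) for c in classes])
    if np.any(counts < 2):
        bad = [c for c, m in zip(classes, counts) if m < 2]
        raise ValueError(f"classes with fewer than 2 samples: {bad} (pooled SD undefined)")

    xbar = X.mean(axis=1)
    cent = np.column_stack([X[:, labels == c].mean(axis=1) for c in classes])

    ss = np.zeros(p)
    for j, c in enumerate(classes):
        resid = X[:, labels == c] - cent[:, [j]]
        ss += (resid**2).sum(axis=1)
    s = np.sqrt(ss / (n - K))

    if s0 is None:
        s0 = float(np.median(s))
    if s0 == 0 and np.any(s == 0):
        raise ValueError(
            "zero-variance feature with s0 = 0; supply a nonzero s0 fudge constant"
        )

    m_k = np.sqrt(1.0 / counts - 1.0 / n)
    denom = m_k[None, :] * (s + s0)[:, None]
    d_raw = (cent - xbar[:, None]) / denom
    d_shrunk = np.sign(d_raw) * np.maximum(np.abs(d_raw) - delta, 0.0)
    shrunken = xbar[:, None] + denom * d_shrunk

    if priors is None:
        priors = counts / n
    else:
        priors = np.asarray(priors, dtype=float)
        if priors.shape != (K,) or np.any(priors <= 0):
            raise ValueError("priors must be positive, one per class")
        priors = priors / priors.sum()

    return NscModel(
        class_labels=classes,
        overall_centroid=xbar,
        class_centroids=cent,
        shrunken_centroids=shrunken,
        pooled_sd=s,
        s0=float(s0),
        m_k=m_k,
        priors=priors,
        delta=float(delta),
        d_raw=d_raw,
        d_shrunk=d_shrunk,
        class_counts=counts,
    )


def _discriminants(model: NscModel, X: np.ndarray) -> np.ndarray:
    """delta_k for each sample; X is (features, samples). Returns (samples, K)."""
    scale = (model.pooled_sd + model.s0)[:, None]
    out = np.empty((X.shape[1], len(model.class_labels)))
    for k in range(len(model.class_labels)):
        z = (X - model.shrunken_centroids[:, [k]]) / scale
        out[:, k] = (z**2).sum(axis=0) - 2.0 * np.log(model.priors[k])
    return out


def classify(model: NscModel, x) -> RiskAssignment | list[RiskAssignment]:
    """Assign sample(s) to the class minimizing the discriminant score.

    ``x`` may be a single feature vector (length p) or a (features, samples)
    matrix, in which case a list is returned.  Exact discriminant ties break
    to the first class in label order (deterministic).
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    p = model.shrunken_centroids.shape[0]
    if single:
        if x.shape[0] != p:
            raise ValueError(f"expected {p} features, got {x.shape[0]}")
        X = x[:, None]
    else:
        X = _as_feature_matrix(x)
        if X.shape[0] != p:
            raise ValueError(f"expected {p} features, got {X.shape[0]}")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature value")

    dd = _discriminants(model, X)
    # softmax of -delta/2, stabilized
    shifted = -(dd - dd.min(axis=1, keepdims=True)) / 2.0
    post = np.exp(shifted)
    post /= post.sum(axis=1, keepdims=True)
    idx = np.argmin(dd, axis=1)  # argmin returns the first minimum: tie -> first label

    out = [
        RiskAssignment(label=model.class_labels[i], posterior=post[j], discriminant=dd[j])
        for j, i in enumerate(idx)
    ]
    return out[0] if single else out


def predict_labels(model: NscModel, X) -> np.ndarray:
    """Vectorized label prediction for a (features, samples) matrix."""
    X = _as_feature_matrix(np.asarray(X, dtype=float))
    dd = _discriminants(model, X)
    idx = np.argmin(dd, axis=1)
    return np.array([model.class_labels[i] for i in idx])


def _stratified_folds(labels, classes, n_folds: int, rng: np.random.Generator):
    """Fold index per sample; each class spread round-robin over folds."""
    fold = np.empty(labels.size, dtype=int)
    for c in classes:
        idx = np.flatnonzero(labels == c)
        idx = rng.permutation(idx)
        fold[idx] = np.arange(idx.size) % n_folds
    return fold


def choose_delta_cv(
    X,
    labels,
    delta_grid=None,
    n_folds: int = 10,
    seed: int = 0,
):
    """Pick the shrinkage by stratified cross-validated misclassification.

    Returns ``(delta_star, curve)`` where ``curve`` maps each grid delta to
    its CV error.  ``delta_star`` is the LARGEST delta attaining the minimum
    error (parsimony tie-break).  Deterministic given the seed.
    """
    X = _as_feature_matrix(X)
    labels = np.asarray(labels)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    classes = sorted(set(labels.tolist()), key=str)
    min_count = min(int(np.sum(labels == c)) for c in classes)
    if n_folds > min_count:
        # a fold would otherwise miss a class entirely; refold with fewer folds
        warnings.warn(
            f"reducing n_folds from {n_folds} to {max(2, min_count)} so every "
            "fold keeps all classes trainable",
            stacklevel=2,
        )
        n_folds = max(2, min_count)

    if delta_grid is None:
        full = fit_nsc(X, labels, delta=0.0)
        delta_grid = np.linspace(0.0, float(np.abs(full.d_raw).max()), 30)
    delta_grid = np.asarray(delta_grid, dtype=float)

    rng = np.random.default_rng(seed)
    fold = _stratified_folds(labels, classes, n_folds, rng)

    errors = np.zeros(delta_grid.size)
    for f in range(n_folds):
        train = fold != f
        test = fold == f
        if test.sum() == 0:
            continue
        base = fit_nsc(X[:, train], labels[train], delta=0.0)
        for gi, dlt in enumerate(delta_grid):
            d_shrunk = np.sign(base.d_raw) * np.maximum(np.abs(base.d_raw) - dlt, 0.0)
            model = NscModel(
                class_labels=base.class_labels,
                overall_centroid=base.overall_centroid,
                class_centroids=base.class_centroids,
                shrunken_centroids=base.overall_centroid[:, None]
                + base.m_k[None, :] * (base.pooled_sd + base.s0)[:, None] * d_shrunk,
                pooled_sd=base.pooled_sd,
                s0=base.s0,
                m_k=base.m_k,
                priors=base.priors,
                delta=float(dlt),
                d_raw=base.d_raw,
                d_shrunk=d_shrunk,
                class_counts=base.class_counts,
            )
            pred = predict_labels(model, X[:, test])
            errors[gi] += int(np.sum(pred != labels[test]))
    errors /= labels.size

    best = errors.min()
    delta_star = float(delta_grid[np.flatnonzero(errors == best)[-1]])
    curve = {"delta": delta_grid.tolist(), "cv_error": errors.tolist()}
    return delta_star, curve


def decision_threshold(model: NscModel) -> float:
    """Scalar decision boundary for a two-class, single-feature model.

    Solves ``delta_1(x) = delta_2(x)`` in closed form; with equal priors this
    is the midpoint of the shrunken centroids.  Scores above the threshold
    belong to the class with the larger shrunken centroid.
    """
    if len(model.class_labels) != 2:
        raise ValueError("threshold defined only for two-class models")
    if model.shrunken_centroids.shape[0] != 1:
        raise ValueError(
            "threshold defined only for single-feature (scalar score) models"
        )
    a, b = model.shrunken_centroids[0, 0], model.shrunken_centroids[0, 1]
    if a == b:
        raise ValueError("shrunken centroids coincide; no unique threshold")
    s = model.pooled_sd[0] + model.s0
    c = 2.0 * s * s * np.log(model.priors[0] / model.priors[1])
    return float((a * a - b * b - c) / (2.0 * (a - b)))
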