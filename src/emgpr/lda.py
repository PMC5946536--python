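"""Linear discriminant analysis with a Gaussian Bayes decision rule.

The motion classifier models each class as a Gaussian with its own mean and
a covariance pooled across classes. Under that model the Bayes-optimal rule
reduces to linear discriminant scores

    g_k(x) = mu_k' Sigma^-1 x - 1/2 mu_k' Sigma^-1 mu_k + ln pi_k

and the predicted motion is the argmax. The pooled covariance is ridged by
``reg_lambda * trace(Sigma)/d * I`` so it is always invertible; ties break
deterministically toward the earlier label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .errors import ConfigError, DataError, ParameterError, TrainingError

DEFAULT_REG_LAMBDA = 1e-6


@dataclass
class LDAModel:
    labels: list[str]
    means: np.ndarray          # (n_classes, n_features)
    pooled_cov: np.ndarray     # (n_features, n_features), already regularized
    priors: np.ndarray         # (n_classes,), sums to 1
    reg_lambda: float = DEFAULT_REG_LAMBDA
    layout: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.pooled_cov = np.asarray(self.pooled_cov, dtype=float)
        self.priors = np.asarray(self.priors, dtype=float)
        if abs(self.priors.sum() - 1.0) > 1e-12:
            raise ConfigError("class priors must sum to 1")
        if self.means.shape != (len(self.labels), self.pooled_cov.shape[0]):
            raise ConfigError("means/labels/covariance dimensions disagree")

    @property
    def n_features(self) -> int:
        return self.means.shape[1]


def fit_lda(X: np.ndarray, y: Sequence[str], priors: Sequence[float] | None = None,
            reg_lambda: float = DEFAULT_REG_LAMBDA,
            layout: dict[str, Any] | None = None) -> LDAModel:
    """Fit class means and a pooled within-class covariance.

    The pooled covariance is the within-class scatter divided by (N - K),
    then ridged with reg_lambda * (trace/d) on the diagonal. Priors default
    to empirical class frequencies; the training protocol records equal time
    per motion, so they are uniform in practice.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not np.all(np.isfinite(X)):
        raise DataError("training features contain non-finite values")
    labels = sorted(set(y.tolist()))
    if len(labels) < 2:
        raise TrainingError(f"need at least 2 classes, got {labels}")
    n, d = X.shape
    means = np.empty((len(labels), d))
    scatter = np.zeros((d, d))
    counts = np.empty(len(labels))
    for k, lab in enumerate(labels):
        Xk = X[y == lab]
        if Xk.shape[0] < 2:
            raise TrainingError(f"class {lab!r} has {Xk.shape[0]} sample(s); need >= 2")
        counts[k] = Xk.shape[0]
        means[k] = Xk.mean(axis=0)
        centered = Xk - means[k]
        scatter += centered.T @ centered
    pooled = scatter / (n - len(labels))
    pooled = pooled + reg_lambda * (np.trace(pooled) / d) * np.eye(d)
    if priors is None:
        pri = counts / n
    else:
        pri = np.asarray(priors, dtype=float)
        pri = pri / pri.sum()
    return LDAModel(labels, means, pooled, pri, reg_lambda, layout or {})


def discriminants(model: LDAModel, x: np.ndarray) -> np.ndarray:
    """Per-class linear discriminant scores, in label order.

    Accepts a single feature vector (d,) or a batch (n, d); returns (K,) or
    (n, K) respectively.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != model.n_features:
        raise ParameterError(
            f"feature dimension {X.shape[1]} != model dimension {model.n_features}"
        )
    chol = cho_factor(model.pooled_cov)
    A = cho_solve(chol, model.means.T)            # (d, K) = Sigma^-1 mu_k
    g = X @ A - 0.5 * np.sum(model.means.T * A, axis=0) + np.log(model.priors)
    return g[0] if single else g


def predict(model: LDAModel, x: np.ndarray) -> str | list[str]:
    """Motion label(s) of maximal discriminant; ties go to the earlier label."""
    g = discriminants(model, x)
    if g.ndim == 1:
        return model.labels[int(np.argmax(g))]
    return [model.labels[k] for k in np.argmax(g, axis=1)]


def save_model(model: LDAModel, path: str | Path) -> None:
    payload = {
        "labels": model.labels,
        "means": model.means.tolist(),
        "pooled_cov": model.pooled_cov.tolist(),
        "priors": model.priors.tolist(),
        "reg_lambda": model.reg_lambda,
        "layout": model.layout,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)
        fh.write("\n")


def load_model(path: str | Path) -> LDAModel:
    with open(path) as fh:
        payload = json.load(fh)
    return LDAModel(
        payload["labels"],
        np.asarray(payload["means"]),
        np.asarray(payload["pooled_cov"]),
        np.asarray(payload["priors"]),
        payload.get("reg_lambda", DEFAULT_REG_LAMBDA),
        payload.get("layout", {}),
    )
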