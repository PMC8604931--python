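"""Discriminant classifiers (LDA, QDA) and the polynomial-kernel SVM.

LDA/QDA are Mahalanobis-distance discriminants: class k scores
``d^2(x, mu_k) - 2 ln pi_k`` under the pooled covariance (LDA) or
``d^2_k(x, mu_k) + ln|Sigma_k| - 2 ln pi_k`` under per-class covariances
(QDA), predicting the argmin.  Singular covariances are ridge-regularized
with ``lambda = 1e-8 * trace(S)/p`` (escalated tenfold until the Cholesky
factorization succeeds) and every such event is logged, never silent.

The SVM is a soft-margin machine with the polynomial kernel
``(x'z + c0)^degree`` (scikit-learn's libsvm backend with gamma fixed at 1
so the kernel matches that form exactly).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

__all__ = [
    "DiscriminantModel",
    "SVMModel",
    "fit_lda",
    "fit_qda",
    "fit_svm",
    "predict",
    "decision_scores",
    "model_to_json",
    "model_from_json",
]


def regularize_covariance(S: np.ndarray, context: str = "") -> tuple[np.ndarray, float]:
    """Return a positive-definite version of ``S`` plus the ridge applied.

    No-op (ridge 0) when ``S`` already factorizes.
    """
    S = np.atleast_2d(np.asarray(S, dtype=float))
    p = S.shape[0]
    try:
        cho_factor(S, lower=True)
        return S, 0.0
    except (LinAlgError, ValueError):
        pass
    lam = 1e-8 * max(np.trace(S), 0.0) / p or 1e-8
    for _ in range(20):
        try:
            cho_factor(S + lam * np.eye(p), lower=True)
            logger.warning(
                "singular covariance%s: ridge lambda=%.3e applied",
                f" ({context})" if context else "", lam,
            )
            return S + lam * np.eye(p), lam
        except (LinAlgError, ValueError):
            lam *= 10.0
    raise np.linalg.LinAlgError(f"covariance{context and f' ({context})'} cannot be regularized")


@dataclass
class DiscriminantModel:
    """Fitted LDA or QDA discriminant."""

    kind: str  # "lda" | "qda"
    classes: list[str]
    means: np.ndarray  # K x d
    priors: np.ndarray  # K
    pooled_cov: np.ndarray | None = None  # lda
    class_covs: np.ndarray | None = None  # qda, K x d x d
    variables: list | None = None
    ridge: float = 0.0


@dataclass
class SVMModel:
    """Fitted polynomial-kernel SVM; keeps the parameters needed to evaluate
    the decision function from a serialized copy."""

    classes: list[str]
    degree: int
    C: float
    c0: float
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    variables: list | None = None
    _svc: SVC | None = field(default=None, repr=False)


def _class_stats(X: np.ndarray, y: np.ndarray):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    classes = sorted(np.unique(y).tolist())
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    means, counts, centered = [], [], []
    for cls in classes:
        rows = X[y == cls]
        if rows.shape[0] < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 rows")
        means.append(rows.mean(axis=0))
        counts.append(rows.shape[0])
        centered.append(rows - rows.mean(axis=0))
    return classes, np.array(means), np.array(counts), centered


def fit_lda(
    X: np.ndarray, y: np.ndarray, priors: str = "empirical",
    variables: list | None = None,
) -> DiscriminantModel:
    """LDA with pooled covariance sum_k (n_k - 1) S_k / (n - K)."""
    classes, means, counts, centered = _class_stats(X, y)
    n, K = counts.sum(), len(classes)
    pooled = sum(c.T @ c for c in centered) / (n - K)
    pooled, ridge = regularize_covariance(pooled, "lda pooled")
    pr = counts / n if priors == "empirical" else np.full(K, 1.0 / K)
    return DiscriminantModel("lda", classes, means, pr, pooled_cov=pooled,
                             variables=variables, ridge=ridge)


def fit_qda(
    X: np.ndarray, y: np.ndarray, priors: str = "empirical",
    variables: list | None = None,
) -> DiscriminantModel:
    """QDA with one covariance per class (ridge-regularized if singular)."""
    classes, means, counts, centered = _class_stats(X, y)
    n, K = counts.sum(), len(classes)
    covs, ridge = [], 0.0
    for cls, c in zip(classes, centered):
        S = c.T @ c / (c.shape[0] - 1)
        S, lam = regularize_covariance(S, f"qda class {cls!r}")
        covs.append(S)
        ridge = max(ridge, lam)
    pr = counts / n if priors == "empirical" else np.full(K, 1.0 / K)
    return DiscriminantModel("qda", classes, means, pr, class_covs=np.array(covs),
                             variables=variables, ridge=ridge)


def covariance_similarity(model: DiscriminantModel) -> float:
    """Diagnostic for QDA: relative Frobenius spread of the class covariances.

    Near 0 means the classes share their variance structure, i.e. QDA has no
    advantage over LDA and may fit its extra parameters to noise.
    """
    if model.class_covs is None:
        raise ValueError("diagnostic requires a QDA model")
    mean_cov = model.class_covs.mean(axis=0)
    denom = np.linalg.norm(mean_cov) or 1.0
    return float(
        max(np.linalg.norm(S - mean_cov) for S in model.class_covs) / denom
    )


def fit_svm(
    X: np.ndarray, y: np.ndarray, degree: int = 2, C: float = 1.0, c0: float = 1.0,
    variables: list | None = None,
) -> SVMModel:
    """Soft-margin SVM with kernel (x'z + c0)^degree; deterministic fit."""
    if degree < 1:
        raise ValueError("degree must be >= 1")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    if len(np.unique(y)) != 2:
        raise ValueError("SVM path supports exactly two classes")
    svc = SVC(kernel="poly", degree=degree, coef0=c0, C=C, gamma=1.0)
    svc.fit(X, y)
    if svc.fit_status_ != 0:
        raise RuntimeError(
            f"SVM optimizer did not converge (libsvm status {svc.fit_status_})"
        )
    return SVMModel(
        classes=[str(c) for c in svc.classes_],
        degree=degree, C=C, c0=c0,
        support_vectors=svc.support_vectors_.copy(),
        dual_coef=svc.dual_coef_[0].copy(),
        intercept=float(svc.intercept_[0]),
        variables=variables, _svc=svc,
    )


def decision_scores(model, X: np.ndarray) -> np.ndarray:
    """Per-row, per-class decision scores; the predicted class is the argmin.

    For LDA/QDA these are the Mahalanobis discriminant scores; for the SVM
    they are (-margin, +margin) oriented so argmin matches the sign rule.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 0:
        return np.empty((0, len(model.classes)))
    d = model.support_vectors.shape[1] if isinstance(model, SVMModel) else model.means.shape[1]
    if X.shape[1] != d:
        raise ValueError(f"column mismatch: model expects {d} variables, got {X.shape[1]}")
    if isinstance(model, SVMModel):
        if model._svc is not None:
            f = model._svc.decision_function(X)
        else:
            K = (X @ model.support_vectors.T + model.c0) ** model.degree
            f = K @ model.dual_coef + model.intercept
        return np.column_stack([f, -f])
    scores = np.empty((X.shape[0], len(model.classes)))
    for k, _ in enumerate(model.classes):
        cov = model.pooled_cov if model.kind == "lda" else model.class_covs[k]
        diff = X - model.means[k]
        factor = cho_factor(cov, lower=True)
        d2 = np.einsum("ij,ji->i", diff, cho_solve(factor, diff.T))
        scores[:, k] = d2 - 2.0 * np.log(model.priors[k])
        if model.kind == "qda":
            sign, logdet = np.linalg.slogdet(cov)
            scores[:, k] += logdet
    return scores


def predict(model, X_new: np.ndarray, return_scores: bool = False):
    """Predicted class labels for new rows (optionally with decision scores)."""
    scores = decision_scores(model, X_new)
    classes = np.asarray(model.classes)
    labels = classes[np.argmin(scores, axis=1)] if scores.size else classes[:0]
    return (labels, scores) if return_scores else labels


# -- JSON serialization ----------------------------------------------------

def model_to_json(model, path: str | Path | None = None) -> str:
    """Serialize a fitted model to a documented JSON schema."""
    if isinstance(model, SVMModel):
        doc = {
            "kind": "svm", "classes": model.classes,
            "degree": model.degree, "C": model.C, "c0": model.c0,
            "support_vectors": model.support_vectors.tolist(),
            "dual_coef": model.dual_coef.tolist(),
            "intercept": model.intercept,
            "variables": model.variables,
        }
    else:
        doc = {
            "kind": model.kind, "classes": model.classes,
            "means": model.means.tolist(), "priors": model.priors.tolist(),
            "pooled_cov": None if model.pooled_cov is None else model.pooled_cov.tolist(),
            "class_covs": None if model.class_covs is None else model.class_covs.tolist(),
            "variables": model.variables, "ridge": model.ridge,
        }
    text = json.dumps(doc)
    if path is not None:
        Path(path).write_text(text)
    return text


def model_from_json(source: str | Path):
    """Rebuild a model serialized by :func:`model_to_json`."""
    if isinstance(source, Path) or not str(source).lstrip().startswith("{"):
        text = Path(source).read_text()
    else:
        text = str(source)
    doc = json.loads(text)
    if doc["kind"] == "svm":
        return SVMModel(
            classes=doc["classes"], degree=doc["degree"], C=doc["C"], c0=doc["c0"],
            support_vectors=np.array(doc["support_vectors"]),
            dual_coef=np.array(doc["dual_coef"]),
            intercept=doc["intercept"], variables=doc["variables"],
        )
    return DiscriminantModel(
        kind=doc["kind"], classes=doc["classes"],
        means=np.array(doc["means"]), priors=np.array(doc["priors"]),
        pooled_cov=None if doc["pooled_cov"] is None else np.array(doc["pooled_cov"]),
        class_covs=None if doc["class_covs"] is None else np.array(doc["class_covs"]),
        variables=doc["variables"], ridge=doc.get("ridge", 0.0),
    )
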