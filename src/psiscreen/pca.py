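"""Exploratory PCA: scores, explained variance, confidence ellipses, and the
difference-between-means (DBM) profile.

PCA is always fitted on training rows only when it feeds a classifier; test
rows are projected through :func:`project`.  Score-plot ellipses use the
chi-square quantile with 2 degrees of freedom (5.991 at 95%), the common
convention for bivariate score plots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2
from sklearn.decomposition import PCA as _SKPCA

from .errors import DegenerateInputError
from .spectra_io import SpectraMatrix

__all__ = [
    "PCAModel",
    "Ellipse",
    "fit_pca",
    "project",
    "confidence_ellipse",
    "difference_between_means",
]


@dataclass
class PCAModel:
    """Fitted PCA: column mean, orthonormal loadings (p x k), training scores
    (n x k) and per-component explained variance in percent of the total."""

    mean: np.ndarray
    loadings: np.ndarray
    scores: np.ndarray
    explained: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def cumulative_explained(self, k: int | None = None) -> float:
        k = self.n_components if k is None else k
        return float(self.explained[:k].sum())


@dataclass(frozen=True)
class Ellipse:
    """Confidence ellipse of a 2-D score cloud."""

    center: np.ndarray
    semi_axes: np.ndarray  # (major, minor)
    rotation: float  # radians, orientation of the major axis
    level: float

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside (or on) the ellipse."""
        pts = np.atleast_2d(points) - self.center
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        R = np.array([[c, s], [-s, c]])
        local = pts @ R.T
        return (local[:, 0] / self.semi_axes[0]) ** 2 + (
            local[:, 1] / self.semi_axes[1]
        ) ** 2 <= 1.0 + 1e-12


def fit_pca(X: np.ndarray, n_components: int) -> PCAModel:
    """Mean-center and decompose; explained % = sigma_k^2 / sum(sigma^2) * 100.

    Sign convention: each loading's largest-magnitude element is positive, so
    score plots and regression tests are stable across library versions.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    max_k = min(n - 1, p)
    if not 1 <= n_components <= max_k:
        raise ValueError(f"n_components must be in [1, {max_k}], got {n_components}")
    if np.allclose(X, X[0], atol=1e-15):
        raise DegenerateInputError("constant matrix has no principal components")
    sk = _SKPCA(n_components=n_components, svd_solver="full")
    scores = sk.fit_transform(X)
    loadings = sk.components_.T.copy()
    explained = sk.explained_variance_ratio_ * 100.0
    for k in range(loadings.shape[1]):
        idx = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[idx, k] < 0:
            loadings[:, k] *= -1.0
            scores[:, k] *= -1.0
    return PCAModel(sk.mean_.copy(), loadings, scores, explained)


def project(model: PCAModel, X_new: np.ndarray) -> np.ndarray:
    """Scores of new rows in the fitted component space: (X - mean) @ loadings."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.mean.size:
        raise ValueError(
            f"column mismatch: model has {model.mean.size} variables, "
            f"input has {X_new.shape[1]}"
        )
    return (X_new - model.mean) @ model.loadings


def inverse_project(model: PCAModel, scores: np.ndarray) -> np.ndarray:
    """Map scores back to the original variable space (rank-k reconstruction)."""
    return np.atleast_2d(scores) @ model.loadings.T + model.mean


def confidence_ellipse(
    scores2: np.ndarray, level: float = 0.95, group: str | None = None
) -> Ellipse:
    """Ellipse covering ``level`` of a bivariate-normal score cloud.

    Axes come from the eigendecomposition of the 2x2 sample covariance scaled
    by the chi-square(2) quantile at ``level`` (5.991 at 0.95).
    """
    pts = np.atleast_2d(np.asarray(scores2, dtype=float))
    if pts.shape[0] < 3 or pts.shape[1] != 2:
        raise ValueError("need an n x 2 block with n >= 3")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    w, v = np.linalg.eigh(cov)
    if w[0] <= 1e-12 * max(w[1], 1e-300):
        who = f" for group {group!r}" if group else ""
        raise DegenerateInputError(f"degenerate score covariance{who}")
    q = chi2.ppf(level, df=2)
    order = [1, 0]  # eigh ascending -> major first
    semi = np.sqrt(w[order] * q)
    major = v[:, 1]
    rotation = float(np.arctan2(major[1], major[0]))
    return Ellipse(center, semi, rotation, level)


def top_loadings(model: PCAModel, mz_axis, k: int = 6):
    """The k variables of largest |loading| per component, as a table.

    A reporting convenience for "variables selected by PCA" summaries; the
    ranking rule (plain loading magnitude) is one convention among several
    and no more than that.
    """
    import pandas as pd

    mz_axis = np.asarray(mz_axis, dtype=float)
    if mz_axis.size != model.loadings.shape[0]:
        raise ValueError("mz_axis length must match the number of variables")
    records = []
    for c in range(model.n_components):
        col = model.loadings[:, c]
        order = np.argsort(-np.abs(col))[:k]
        for rank, idx in enumerate(order):
            records.append({"component": f"PC{c + 1}", "rank": rank + 1,
                            "mz": float(mz_axis[idx]),
                            "loading": float(col[idx])})
    return pd.DataFrame.from_records(records)


def difference_between_means(
    m: SpectraMatrix,
    case_label: str | None = None,
    control_label: str | None = None,
) -> np.ndarray:
    """Per-variable difference of class mean spectra: mean(case) - mean(control).

    With the default "control"/"case" labels the orientation is inferred; for
    any other label pair both names must be given explicitly.
    """
    classes = m.classes()
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, found {classes}")
    if case_label is None or control_label is None:
        if set(classes) == {"control", "case"}:
            case_label, control_label = "case", "control"
        else:
            raise ValueError(
                f"labels {classes} are not control/case; pass case_label and "
                "control_label explicitly"
            )
    y = m.labels()
    case_rows = m.X[y == case_label]
    control_rows = m.X[y == control_label]
    if case_rows.shape[0] == 0 or control_rows.shape[0] == 0:
        raise ValueError("one of the classes has no spectra")
    return case_rows.mean(axis=0) - control_rows.mean(axis=0)
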