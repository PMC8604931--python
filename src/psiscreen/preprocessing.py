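"""Spectral preprocessing: AWLS baseline correction, then vector normalization.

The baseline estimator is an automatic weighted least-squares (AWLS)
polynomial fit: points above the current fit — peaks — are exponentially
down-weighted, points on or below it keep full weight, and the fit is
iterated to convergence.  Corrected intensities are *not* clipped at zero
(clipping would bias the subsequent unit-norm scaling); users who need
non-negative spectra can clip explicitly.  The two steps always run in this
order: baseline first, normalization second.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .errors import DegenerateInputError
from .spectra_io import SpectraMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig",
    "awls_baseline",
    "vector_normalize",
    "preprocess_matrix",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Baseline/normalization settings.

    baseline_order : polynomial order of the baseline (2 suits the smooth
        drift of ambient-MS chemical noise).
    baseline_max_iter / baseline_tol : iteration cap and relative convergence
        tolerance on the fitted baseline.
    normalize : scale each corrected spectrum to unit Euclidean norm.
    """

    baseline_order: int = 2
    baseline_max_iter: int = 100
    baseline_tol: float = 1e-6
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.baseline_order < 0:
            raise ValueError("baseline_order must be >= 0")
        if self.baseline_max_iter < 1:
            raise ValueError("baseline_max_iter must be >= 1")
        if self.baseline_tol <= 0:
            raise ValueError("baseline_tol must be positive")


def _awls_batch(
    Y: np.ndarray, order: int, max_iter: int, tol: float, x: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    """Fit AWLS baselines to every row of ``Y``; returns (baselines, n_iter).

    Weight update per row: w_i = 1 where y_i <= b_i, else exp(-(y_i - b_i)/s)
    with s the standard deviation of the negative residuals.  Convergence is
    max |b_new - b_old| relative to the baseline's magnitude.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n, p = Y.shape
    if p < order + 1:
        raise ValueError(f"need at least order+1={order + 1} points, got {p}")
    if x is None:
        x = np.arange(p, dtype=float)
    # Scale the abscissa to [-1, 1] for a well-conditioned Vandermonde basis.
    half = (x[-1] - x[0]) / 2 or 1.0
    t = (x - (x[0] + x[-1]) / 2) / half
    V = np.polynomial.polynomial.polyvander(t, order)  # p x (order+1)

    W = np.ones_like(Y)
    B = np.zeros_like(Y)
    iters = np.full(n, max_iter, dtype=int)
    active = np.ones(n, dtype=bool)
    eye = np.eye(order + 1)
    for it in range(1, max_iter + 1):
        A = np.einsum("pi,np,pj->nij", V, W, V)
        rhs = np.einsum("pi,np->ni", V, W * Y)
        coef = np.linalg.solve(A + 1e-12 * eye, rhs[:, :, None])[:, :, 0]
        B_new = coef @ V.T
        scale = np.maximum(np.abs(B_new).max(axis=1), 1e-12)
        delta = np.abs(B_new - B).max(axis=1) / scale
        B = B_new
        newly = active & (delta < tol) & (it > 1)
        iters[newly] = it
        active &= ~newly
        if not active.any():
            break
        r = Y - B
        neg = r < 0
        cnt = neg.sum(axis=1)
        s = np.sqrt(
            np.where(cnt > 0, (np.where(neg, r, 0.0) ** 2).sum(axis=1) / np.maximum(cnt, 1), 0.0)
        )
        s = np.maximum(s, 1e-12)[:, None]
        W = np.where(r <= 0, 1.0, np.exp(-r / s))
    return B, iters


def awls_baseline(
    y: np.ndarray, cfg: PreprocessConfig | None = None, x: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """AWLS baseline of a single spectrum; returns (corrected, baseline).

    ``x`` are the abscissa values (defaults to the sample index; for a uniform
    m/z grid the two choices span the same polynomial space).  Corrected
    values may be slightly negative and are intentionally not clipped.
    """
    cfg = cfg or PreprocessConfig()
    y = np.asarray(y, dtype=float)
    B, _ = _awls_batch(y[None, :], cfg.baseline_order, cfg.baseline_max_iter,
                       cfg.baseline_tol, x)
    baseline = B[0]
    return y - baseline, baseline


def vector_normalize(y: np.ndarray, spectrum_id: str | None = None) -> np.ndarray:
    """Scale a spectrum to unit Euclidean norm."""
    y = np.asarray(y, dtype=float)
    norm = float(np.linalg.norm(y))
    if norm == 0.0 or not np.isfinite(norm):
        who = f" (spectrum {spectrum_id!r})" if spectrum_id else ""
        raise DegenerateInputError(f"cannot normalize zero/non-finite spectrum{who}")
    return y / norm


def preprocess_matrix(m: SpectraMatrix, cfg: PreprocessConfig | None = None) -> SpectraMatrix:
    """Baseline-correct then (optionally) unit-normalize every row.

    The m/z axis, ids and replicate structure are unchanged; per-spectrum
    iteration counts go to the module log.  Row-level failures are re-raised
    with the offending spectrum id.
    """
    cfg = cfg or PreprocessConfig()
    B, iters = _awls_batch(m.X, cfg.baseline_order, cfg.baseline_max_iter,
                           cfg.baseline_tol, m.mz_axis)
    corrected = m.X - B
    logger.info(
        "preprocess_matrix: AWLS order=%d, iterations median=%d max=%d",
        cfg.baseline_order, int(np.median(iters)), int(iters.max()),
    )
    if cfg.normalize:
        # A spectrum that is pure baseline corrects to numerical noise; unit
        # scaling would amplify it into garbage, so treat it as degenerate.
        orig_norms = np.linalg.norm(m.X, axis=1)
        rows = np.empty_like(corrected)
        for i, sid in enumerate(m.spectrum_ids):
            if np.linalg.norm(corrected[i]) < 1e-9 * max(orig_norms[i], 1e-300):
                raise DegenerateInputError(
                    f"spectrum {sid!r} is indistinguishable from its baseline "
                    "(corrected signal ~ 0); cannot normalize"
                )
            rows[i] = vector_normalize(corrected[i], spectrum_id=sid)
        corrected = rows
    return replace(m, X=corrected)
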