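"""Kennard-Stone maximin selection and the train/test split.

Kennard-Stone picks a representative subset deterministically: start from the
two most distant points, then repeatedly add the point whose minimum distance
to the selected set is largest.  The pipeline's split runs it per class at
subject level (on replicate-averaged rows), so that all replicates of one
subject land on the same side — replicate leakage across the split would
inflate test accuracy.  A ``level="spectrum"`` escape hatch mimics the laxer
per-spectrum reading.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .spectra_io import SpectraMatrix, average_replicates

__all__ = ["Split", "kennard_stone", "split_train_test", "round_half_up"]


def round_half_up(value: float) -> int:
    return int(np.floor(value + 0.5))


@dataclass(frozen=True)
class Split:
    """Row indices of the training and test sides of a split."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    fraction: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "train_idx", np.asarray(self.train_idx, dtype=int))
        object.__setattr__(self, "test_idx", np.asarray(self.test_idx, dtype=int))
        overlap = np.intersect1d(self.train_idx, self.test_idx)
        if overlap.size:
            raise ValueError(f"train/test overlap at rows {overlap[:5]}")


def kennard_stone(X: np.ndarray, n_select: int) -> np.ndarray:
    """Deterministic maximin selection; returns indices in selection order.

    The first two picks realize the maximal pairwise Euclidean distance; every
    later pick maximizes the minimum distance to the already-selected set.
    Ties break toward the lowest row index (duplicate rows are allowed).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if n_select < 2:
        raise ValueError("n_select must be at least 2")
    if n_select > n:
        raise ValueError(f"n_select ({n_select}) exceeds number of rows ({n})")
    D = cdist(X, X)
    # Row-major argmax lands on the lexicographically smallest (i, j) pair.
    i, j = np.unravel_index(int(np.argmax(D)), D.shape)
    selected = [min(i, j), max(i, j)]
    min_dist = np.minimum(D[selected[0]], D[selected[1]])
    chosen = np.zeros(n, dtype=bool)
    chosen[selected] = True
    while len(selected) < n_select:
        cand = np.where(chosen, -np.inf, min_dist)
        pick = int(np.argmax(cand))  # first max -> lowest index on ties
        selected.append(pick)
        chosen[pick] = True
        min_dist = np.minimum(min_dist, D[pick])
    return np.array(selected, dtype=int)


def split_train_test(
    m: SpectraMatrix, fraction: float, level: str = "subject"
) -> Split:
    """Kennard-Stone 70/30-style split, run separately within each class.

    At ``level="subject"`` (default) selection operates on replicate-averaged
    rows and every replicate inherits its subject's assignment.  The per-class
    training count is ``round_half_up(fraction * n_class)``.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    if level not in ("subject", "spectrum"):
        raise ValueError(f"unknown split level {level!r}")
    labels = m.labels()
    train_rows: list[int] = []
    test_rows: list[int] = []
    if level == "subject":
        avg = average_replicates(m)
        avg_labels = avg.labels()
        per_row_subject = m.subject_ids_per_row()
        for cls in m.classes():
            rows = np.flatnonzero(avg_labels == cls)
            if rows.size < 2:
                raise ValueError(f"class {cls!r} has fewer than 2 subjects")
            n_tr = round_half_up(fraction * rows.size)
            if n_tr < 2:
                raise ValueError(
                    f"class {cls!r}: fraction {fraction} leaves fewer than 2 "
                    "training subjects"
                )
            sel = kennard_stone(avg.X[rows], n_tr)
            chosen = {avg.spectrum_ids[rows[k]] for k in sel}
            for idx in np.flatnonzero(labels == cls):
                (train_rows if per_row_subject[idx] in chosen else test_rows).append(idx)
    else:
        for cls in m.classes():
            rows = np.flatnonzero(labels == cls)
            if rows.size < 2:
                raise ValueError(f"class {cls!r} has fewer than 2 spectra")
            n_tr = round_half_up(fraction * rows.size)
            if n_tr < 2:
                raise ValueError(
                    f"class {cls!r}: fraction {fraction} leaves fewer than 2 "
                    "training spectra"
                )
            sel = kennard_stone(m.X[rows], n_tr)
            sel_rows = set(rows[sel].tolist())
            for idx in rows:
                (train_rows if idx in sel_rows else test_rows).append(idx)
    return Split(np.sort(train_rows), np.sort(test_rows), fraction)
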