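"""Score-plot and explained-variance exports."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .errors import DegenerateInputError
from .pca import PCAModel, confidence_ellipse

__all__ = ["score_plot", "explained_variance_table"]


def score_plot(
    model: PCAModel,
    labels,
    path: str | Path,
    level: float = 0.95,
    components: tuple[int, int] = (0, 1),
) -> None:
    """PC-vs-PC score scatter with a per-class confidence ellipse (SVG/PNG)."""
    labels = np.asarray(labels)
    i, j = components
    scores = model.scores[:, [i, j]]
    fig, ax = plt.subplots(figsize=(6, 5))
    for cls in sorted(set(labels.tolist())):
        pts = scores[labels == cls]
        ax.scatter(pts[:, 0], pts[:, 1], label=str(cls), alpha=0.8)
        try:
            ell = confidence_ellipse(pts, level=level, group=str(cls))
        except (ValueError, DegenerateInputError):
            continue
        theta = np.linspace(0, 2 * np.pi, 200)
        circle = np.column_stack([
            ell.semi_axes[0] * np.cos(theta), ell.semi_axes[1] * np.sin(theta)
        ])
        c, s = np.cos(ell.rotation), np.sin(ell.rotation)
        rot = circle @ np.array([[c, s], [-s, c]])
        ax.plot(rot[:, 0] + ell.center[0], rot[:, 1] + ell.center[1],
                linestyle="dotted")
    ax.set_xlabel(f"PC{i + 1} ({model.explained[i]:.2f}%)")
    ax.set_ylabel(f"PC{j + 1} ({model.explained[j]:.2f}%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def explained_variance_table(model: PCAModel, path: str | Path | None = None) -> pd.DataFrame:
    """Per-component and cumulative explained variance (%), optionally to CSV."""
    frame = pd.DataFrame({
        "component": [f"PC{k + 1}" for k in range(model.n_components)],
        "explained_pct": model.explained,
        "cumulative_pct": np.cumsum(model.explained),
    })
    if path is not None:
        frame.to_csv(path, index=False)
    return frame
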