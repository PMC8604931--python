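"""YAML pipeline configuration.

Recognized blocks::

    preprocess: {order: 2, max_iter: 100, tol: 1e-6, normalize: true}
    split:      {fraction: 0.7, level: subject}
    grid:       {n_components: 5, spa_max_vars: 5, svm_degree: 2,
                 svm_C: 1.0, svm_c0: 1.0, seed: 0}
    ga:         {population: 40, generations: 80, crossover: 0.6,
                 mutation: 0.005, max_vars: 15, n_runs: 3}
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .evaluation import GridConfig
from .preprocessing import PreprocessConfig
from .variable_selection import GAConfig

__all__ = ["PipelineConfig", "load_pipeline_config"]


class PipelineConfig:
    """Bundle of the per-stage configuration dataclasses."""

    def __init__(self, preprocess: PreprocessConfig, grid: GridConfig):
        self.preprocess = preprocess
        self.grid = grid

    @classmethod
    def default(cls) -> "PipelineConfig":
        return cls(PreprocessConfig(), GridConfig())


def load_pipeline_config(path: str | Path | None) -> PipelineConfig:
    if path is None:
        return PipelineConfig.default()
    doc = yaml.safe_load(Path(path).read_text()) or {}
    pre = doc.get("preprocess", {})
    preprocess = PreprocessConfig(
        baseline_order=int(pre.get("order", 2)),
        baseline_max_iter=int(pre.get("max_iter", 100)),
        baseline_tol=float(pre.get("tol", 1e-6)),
        normalize=bool(pre.get("normalize", True)),
    )
    ga_doc = doc.get("ga", {})
    ga = GAConfig(
        population=int(ga_doc.get("population", 40)),
        generations=int(ga_doc.get("generations", 80)),
        crossover=float(ga_doc.get("crossover", 0.6)),
        mutation=float(ga_doc.get("mutation", 0.005)),
        max_vars=int(ga_doc.get("max_vars", 15)),
        n_runs=int(ga_doc.get("n_runs", 3)),
    )
    grid_doc = doc.get("grid", {})
    split_doc = doc.get("split", {})
    grid = GridConfig(
        n_components=int(grid_doc.get("n_components", 5)),
        spa_max_vars=int(grid_doc.get("spa_max_vars", 5)),
        ga=ga,
        svm_degree=int(grid_doc.get("svm_degree", 2)),
        svm_C=float(grid_doc.get("svm_C", 1.0)),
        svm_c0=float(grid_doc.get("svm_c0", 1.0)),
        split_fraction=float(split_doc.get("fraction", 0.7)),
        split_level=str(split_doc.get("level", "subject")),
        seed=int(grid_doc.get("seed", 0)),
    )
    return PipelineConfig(preprocess, grid)
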