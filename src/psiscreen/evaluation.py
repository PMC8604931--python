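"""Figures of merit, the nine-model comparison grid, and validation checks.

The grid crosses three reductions (PCA scores, SPA selection, GA selection)
with three classifiers (LDA, QDA, polynomial-kernel SVM).  Every row shares
one Kennard-Stone train/test split; variable selection never sees the test
rows — a further 70/30 Kennard-Stone carve inside the training side provides
the fit/validation partition that scores candidate subsets.

Two confounding checks are provided: the label-swap test (refit everything
with the two class names exchanged; a sound deterministic pipeline swaps its
per-class metrics exactly) and a permutation null (subject labels shuffled,
replicates moving with their subject, p-value with the (b+1)/(n+1) rule).
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifiers import fit_lda, fit_qda, fit_svm, predict
from .sample_selection import Split, split_train_test
from .spectra_io import SpectraMatrix
from .variable_selection import (
    GAConfig,
    SelectionResult,
    ga_select,
    pca_reduce,
    spa_all_chains,
    spa_select,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ClassMetrics",
    "FiguresOfMerit",
    "GridConfig",
    "GridRow",
    "ModelGridReport",
    "MODEL_NAMES",
    "figures_of_merit",
    "run_model_grid",
    "run_single_model",
    "label_swap_test",
    "permutation_null",
]

MODEL_NAMES = (
    "PCA-LDA", "PCA-QDA", "PCA-SVM",
    "SPA-LDA", "SPA-QDA", "SPA-SVM",
    "GA-LDA", "GA-QDA", "GA-SVM",
)

_TIE = "__tie__"  # sentinel predicted label for tied subject-level votes


@dataclass(frozen=True)
class ClassMetrics:
    """Confusion counts for one class treated as positive, plus derived %."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def accuracy(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.n if self.n else float("nan")


@dataclass(frozen=True)
class FiguresOfMerit:
    """Per-class figures of merit at a stated counting level."""

    per_class: dict[str, ClassMetrics]
    level: str  # "spectrum" | "subject"
    n_items: int

    def __getitem__(self, cls: str) -> ClassMetrics:
        return self.per_class[cls]


def figures_of_merit(
    y_true,
    y_pred,
    level: str = "spectrum",
    subjects=None,
) -> FiguresOfMerit:
    """Exact integer confusion counts per class and the derived percentages.

    ``level="subject"`` majority-votes the replicate predictions of each
    subject (``subjects`` maps each item to its subject id); tied votes count
    as misclassifications and are logged.  A class absent from ``y_true``
    yields NaN metrics with a warning, never a silent zero.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    if level not in ("spectrum", "subject"):
        raise ValueError(f"unknown counting level {level!r}")
    if level == "subject":
        if subjects is None:
            raise ValueError("subject-level counting requires the replicate map")
        subjects = np.asarray(subjects)
        t_list, p_list = [], []
        for subj in dict.fromkeys(subjects.tolist()):
            rows = subjects == subj
            truths = set(y_true[rows].tolist())
            if len(truths) != 1:
                raise ValueError(f"subject {subj!r} has inconsistent true labels")
            votes = pd.Series(y_pred[rows]).value_counts()
            top = votes[votes == votes.max()]
            if len(top) == 1:
                vote = top.index[0]
            else:
                vote = _TIE
                logger.info("figures_of_merit: tied vote for subject %r "
                            "counted as misclassified", subj)
            t_list.append(next(iter(truths)))
            p_list.append(vote)
        y_true, y_pred = np.asarray(t_list), np.asarray(p_list)
    classes = sorted(set(y_true.tolist()) | (set(y_pred.tolist()) - {_TIE}))
    per_class: dict[str, ClassMetrics] = {}
    for cls in classes:
        tp = int(np.sum((y_true == cls) & (y_pred == cls)))
        fn = int(np.sum((y_true == cls) & (y_pred != cls)))
        fp = int(np.sum((y_true != cls) & (y_pred == cls)))
        tn = int(np.sum((y_true != cls) & (y_pred != cls)))
        if tp + fn == 0:
            warnings.warn(f"class {cls!r} absent from y_true: sensitivity undefined")
        per_class[cls] = ClassMetrics(tp, tn, fp, fn)
    return FiguresOfMerit(per_class, level, int(y_true.size))


@dataclass(frozen=True)
class GridConfig:
    """Settings shared by all nine grid models."""

    n_components: int = 5
    spa_max_vars: int = 5
    ga: GAConfig = field(default_factory=GAConfig)
    svm_degree: int = 2
    svm_C: float = 1.0
    svm_c0: float = 1.0
    split_fraction: float = 0.7
    split_level: str = "subject"
    selection_fit_fraction: float = 0.7  # training-side carve: fit vs validation
    seed: int = 0

    def svm_params(self) -> dict:
        return {"degree": self.svm_degree, "C": self.svm_C, "c0": self.svm_c0}

    def hash(self) -> str:
        return hashlib.md5(repr(self).encode()).hexdigest()[:12]


@dataclass
class GridRow:
    """One model's results in the nine-model comparison."""

    name: str
    reduction: str
    classifier: str
    fom_spectrum: FiguresOfMerit | None = None
    fom_subject: FiguresOfMerit | None = None
    selection: SelectionResult | None = None
    seeds: list[int] = field(default_factory=list)
    config_hash: str = ""
    error: str | None = None

    @property
    def accuracy(self) -> float:
        if self.fom_spectrum is None:
            return float("nan")
        first = next(iter(self.fom_spectrum.per_class.values()))
        return first.accuracy


@dataclass
class ModelGridReport:
    rows: list[GridRow]

    def row(self, name: str) -> GridRow:
        for r in self.rows:
            if r.name == name:
                return r
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        """Table-shaped report: per-class sensitivity/specificity per model."""
        records = []
        for r in self.rows:
            rec: dict = {"model": r.name, "error": r.error or ""}
            if r.fom_spectrum is not None:
                for cls, met in r.fom_spectrum.per_class.items():
                    rec[f"{cls}_sensitivity_pct"] = round(met.sensitivity, 2)
                    rec[f"{cls}_specificity_pct"] = round(met.specificity, 2)
                rec["accuracy_pct"] = round(r.accuracy, 2)
            if r.selection is not None:
                rec["variables_mz"] = " ".join(f"{v:g}" for v in r.selection.variables)
            records.append(rec)
        return pd.DataFrame.from_records(records)

    def selection_frame(self) -> pd.DataFrame:
        """Per-run selected-variable table across SPA/GA models."""
        records = []
        for r in self.rows:
            if r.selection is None:
                continue
            for run, (variables, cost) in enumerate(
                zip(r.selection.per_run_variables, r.selection.per_run_costs)
            ):
                records.append({
                    "model": r.name, "run": run,
                    "seed": (r.selection.seeds[run]
                             if run < len(r.selection.seeds) else ""),
                    "variables_mz": " ".join(f"{v:g}" for v in variables),
                    "cost": cost,
                })
        return pd.DataFrame.from_records(records)


class _GridContext:
    """Shared state for the nine models: split sides, selection carve, caches."""

    def __init__(self, m: SpectraMatrix, split: Split, cfg: GridConfig):
        self.m, self.split, self.cfg = m, split, cfg
        self.train = m.subset(split.train_idx)
        self.test = m.subset(split.test_idx)
        self.ytr, self.yte = self.train.labels(), self.test.labels()
        carve = split_train_test(self.train, cfg.selection_fit_fraction,
                                 level=cfg.split_level)
        self.fit_m = self.train.subset(carve.train_idx)
        self.val_m = self.train.subset(carve.test_idx)
        self.yfit, self.yval = self.fit_m.labels(), self.val_m.labels()
        self._chains: list[list[int]] | None = None
        self._selection: dict[tuple[str, str], SelectionResult] = {}

    @property
    def chains(self) -> list[list[int]]:
        if self._chains is None:
            max_len = min(self.cfg.spa_max_vars,
                          self.fit_m.n_spectra - 1, self.fit_m.n_variables)
            self._chains = spa_all_chains(self.fit_m.X, max_len)
        return self._chains

    def selection(self, reduction: str, classifier: str) -> SelectionResult:
        # LDA and QDA couplings share the Mahalanobis risk cost, hence the
        # same selection; SVM couplings use the validation error rate.
        cost_kind = "svm" if classifier == "svm" else "lda"
        key = (reduction, cost_kind)
        if key not in self._selection:
            if reduction == "spa":
                self._selection[key] = spa_select(
                    self.fit_m.X, self.yfit, self.val_m.X, self.yval,
                    max_vars=self.cfg.spa_max_vars, classifier=cost_kind,
                    mz_axis=self.fit_m.mz_axis, chains=self.chains,
                    svm_params=self.cfg.svm_params(),
                )
            elif reduction == "ga":
                self._selection[key] = ga_select(
                    self.fit_m.X, self.yfit, self.val_m.X, self.yval,
                    cfg=self.cfg.ga, seed=self.cfg.seed, classifier=cost_kind,
                    mz_axis=self.fit_m.mz_axis, svm_params=self.cfg.svm_params(),
                )
            else:
                raise ValueError(f"unknown reduction {reduction!r}")
        return self._selection[key]


def _fit_predict(classifier: str, cfg: GridConfig, Xtr, ytr, Xte, variables=None):
    if classifier == "lda":
        model = fit_lda(Xtr, ytr, variables=variables)
    elif classifier == "qda":
        model = fit_qda(Xtr, ytr, variables=variables)
    elif classifier == "svm":
        model = fit_svm(Xtr, ytr, variables=variables, **cfg.svm_params())
    else:
        raise ValueError(f"unknown classifier {classifier!r}")
    return predict(model, Xte)


def _run_row(ctx: _GridContext, name: str) -> GridRow:
    reduction, classifier = name.split("-")
    reduction, classifier = reduction.lower(), classifier.lower()
    row = GridRow(name=name, reduction=reduction, classifier=classifier,
                  config_hash=ctx.cfg.hash())
    try:
        selection = None
        if reduction == "pca":
            tr, te, _ = pca_reduce(ctx.train.X, ctx.test.X, ctx.cfg.n_components)
            y_pred = _fit_predict(classifier, ctx.cfg, tr, ctx.ytr, te,
                                  variables=[f"PC{i+1}" for i in range(tr.shape[1])])
        else:
            selection = ctx.selection(reduction, classifier)
            cols = selection.indices
            y_pred = _fit_predict(
                classifier, ctx.cfg, ctx.train.X[:, cols], ctx.ytr,
                ctx.test.X[:, cols], variables=selection.variables,
            )
        row.selection = selection
        row.seeds = list(selection.seeds) if selection else []
        row.fom_spectrum = figures_of_merit(ctx.yte, y_pred, level="spectrum")
        row.fom_subject = figures_of_merit(
            ctx.yte, y_pred, level="subject",
            subjects=ctx.test.subject_ids_per_row(),
        )
    except Exception as exc:  # a single model's failure must not stop the grid
        logger.warning("model %s failed: %s", name, exc)
        row.error = f"{type(exc).__name__}: {exc}"
    return row


def run_model_grid(
    m: SpectraMatrix, split: Split, cfg: GridConfig | None = None
) -> ModelGridReport:
    """Train and evaluate all nine reduction x classifier combinations.

    Expects a preprocessed matrix; every row uses the same split.  Individual
    model failures are recorded in their row and the grid continues.
    """
    cfg = cfg or GridConfig()
    ctx = _GridContext(m, split, cfg)
    return ModelGridReport([_run_row(ctx, name) for name in MODEL_NAMES])


def run_single_model(
    m: SpectraMatrix,
    split: Split | None,
    cfg: GridConfig,
    model_name: str,
) -> GridRow:
    """One grid row on its own (computing the split if not supplied)."""
    if model_name not in MODEL_NAMES:
        raise ValueError(f"unknown model {model_name!r}; choose from {MODEL_NAMES}")
    if split is None:
        split = split_train_test(m, cfg.split_fraction, level=cfg.split_level)
    ctx = _GridContext(m, split, cfg)
    row = _run_row(ctx, model_name)
    if row.error is not None:
        raise RuntimeError(f"model {model_name} failed: {row.error}")
    return row


@dataclass
class SwapReport:
    """Results of the label-swap confounding test."""

    original: GridRow
    swapped: GridRow
    label_map: dict[str, str]


def label_swap_test(
    m: SpectraMatrix, split: Split, cfg: GridConfig, model_name: str
) -> SwapReport:
    """Re-run the pipeline with the two class labels mutually exchanged.

    Selection and classification are redone from scratch on the swapped
    labels.  For a deterministic model the per-class figures of merit of the
    two runs exchange roles exactly (class A's metrics in the original run
    equal class B's in the swapped run).
    """
    classes = m.classes()
    if len(classes) != 2:
        raise ValueError("label swap requires exactly two classes")
    a, b = classes
    label_map = {a: b, b: a}
    swapped_classes = {s: label_map[c] for s, c in m.class_of.items()}
    m_swapped = m.with_class_of(swapped_classes)
    original = run_single_model(m, split, cfg, model_name)
    swapped = run_single_model(m_swapped, split, cfg, model_name)
    return SwapReport(original, swapped, label_map)


@dataclass
class PermutationResult:
    observed_accuracy: float
    null_accuracies: np.ndarray
    p_value: float
    n_perm: int


def permutation_null(
    m: SpectraMatrix,
    split: Split,
    cfg: GridConfig,
    model_name: str,
    n_perm: int,
    seed: int = 0,
) -> PermutationResult:
    """Permutation control: shuffle subject labels and re-run the pipeline.

    Replicates move with their subject.  Each permutation recomputes the
    Kennard-Stone split (class membership changed), the selection and the
    fit.  p-value: (1 + #{null >= observed}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed = run_single_model(m, split, cfg, model_name)
    obs_acc = observed.accuracy
    rng = np.random.default_rng(seed)
    subjects = m.subjects
    labels = [m.class_of[s] for s in subjects]
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(len(subjects))
        class_of = {subjects[i]: labels[perm[i]] for i in range(len(subjects))}
        mb = m.with_class_of(class_of)
        row = run_single_model(mb, None, cfg, model_name)
        null[b] = row.accuracy
    p = (1.0 + float(np.sum(null >= obs_acc - 1e-12))) / (n_perm + 1.0)
    return PermutationResult(obs_acc, null, p, n_perm)
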