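"""Variable reduction: SPA and GA selection, and PCA score reduction.

Candidate variable subsets are scored on a validation partition that is
disjoint from the rows used to fit the discriminant: for LDA/QDA couplings
the cost is the Mahalanobis risk ratio G (mean over validation rows of
``d^2(x, mu_own) / min_m d^2(x, mu_m)`` under the pooled covariance — small
when classes are tight and far apart); for SVM couplings it is the
validation error rate, since G presumes class-mean/covariance structure an
SVM does not use.

SPA (successive projections algorithm) is fully deterministic: from each
starting column it grows a chain by repeatedly appending the column with the
largest norm after projection onto the orthogonal complement of the chosen
span, then every chain prefix is scored and the global minimizer returned.
The GA evolves binary chromosomes (bit = variable included) with tournament
selection, one-point crossover, bit-flip mutation and single elitism; being
stochastic it is run three times by default and all runs are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve

from .classifiers import fit_svm, predict
from .pca import PCAModel, fit_pca, project

logger = logging.getLogger(__name__)

__all__ = [
    "GAConfig",
    "SelectionResult",
    "risk_cost",
    "spa_chains",
    "spa_all_chains",
    "spa_select",
    "ga_select",
    "pca_reduce",
]


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings (all dimensionless).

    ``mutation`` is the per-bit flip probability; ``penalty`` is the fitness
    cost per active variable beyond ``max_vars``; ``init_active`` the expected
    number of active bits in a fresh chromosome (sparse initialization keeps
    early covariances invertible).
    """

    population: int = 40
    generations: int = 80
    crossover: float = 0.6
    # Per-bit flip probability.  ~5 expected flips on a 950-bit chromosome
    # (the 1/L..5/L range GA practice recommends); much higher rates turn the
    # search into a random walk that cannot refine sparse solutions.
    mutation: float = 0.005
    max_vars: int = 15
    penalty: float = 0.1
    init_active: int = 8
    n_runs: int = 3

    def __post_init__(self) -> None:
        if self.population < 2 or self.generations < 1:
            raise ValueError("population >= 2 and generations >= 1 required")
        if not (0 <= self.crossover <= 1 and 0 <= self.mutation <= 1):
            raise ValueError("crossover and mutation must be probabilities")
        if self.max_vars < 1 or self.n_runs < 1:
            raise ValueError("max_vars and n_runs must be >= 1")


@dataclass
class SelectionResult:
    """Outcome of a variable-selection run (SPA or GA)."""

    variables: list[float]  # m/z values, in selection order
    indices: list[int]  # column indices into the source matrix
    cost: float
    n_runs: int
    seeds: list[int]
    per_run_variables: list[list[float]]
    per_run_costs: list[float]
    method: str

    @property
    def union_variables(self) -> list[float]:
        out: dict[float, None] = {}
        for run in self.per_run_variables:
            for v in run:
                out.setdefault(v, None)
        return sorted(out)


def risk_cost(
    Xval: np.ndarray,
    yval: np.ndarray,
    means: dict[str, np.ndarray],
    pooled_cov: np.ndarray,
) -> float:
    """Mahalanobis risk ratio G averaged over the validation rows.

    Per row: squared Mahalanobis distance to its own class mean divided by the
    smallest squared distance to any other class mean.  A singular pooled
    covariance rejects the candidate subset (cost +inf, logged).
    """
    Xval = np.atleast_2d(np.asarray(Xval, dtype=float))
    yval = np.asarray(yval)
    classes = sorted(means)
    try:
        factor = cho_factor(np.atleast_2d(pooled_cov), lower=True)
    except (LinAlgError, ValueError):
        logger.debug("risk_cost: singular pooled covariance, candidate rejected")
        return float("inf")
    d2 = np.empty((Xval.shape[0], len(classes)))
    for k, cls in enumerate(classes):
        diff = Xval - np.asarray(means[cls], dtype=float)
        d2[:, k] = np.einsum("ij,ji->i", diff, cho_solve(factor, diff.T))
    own_idx = np.array([classes.index(c) for c in yval])
    own = d2[np.arange(len(yval)), own_idx]
    other = d2.copy()
    other[np.arange(len(yval)), own_idx] = np.inf
    nearest_other = other.min(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(nearest_other > 0, own / nearest_other,
                     np.where(own == 0, 1.0, np.inf))
    return float(np.mean(g))


def _pooled_stats(X: np.ndarray, y: np.ndarray):
    classes = sorted(np.unique(y).tolist())
    means: dict[str, np.ndarray] = {}
    pooled = np.zeros((X.shape[1], X.shape[1]))
    n = 0
    for cls in classes:
        rows = X[y == cls]
        mu = rows.mean(axis=0)
        means[cls] = mu
        c = rows - mu
        pooled += c.T @ c
        n += rows.shape[0]
    pooled /= max(n - len(classes), 1)
    return means, pooled


def _candidate_cost(
    Xfit, yfit, Xval, yval, cols, classifier: str, svm_params: dict | None
) -> float:
    cols = list(cols)
    if classifier in ("lda", "qda"):
        means, pooled = _pooled_stats(Xfit[:, cols], yfit)
        return risk_cost(Xval[:, cols], yval, means, pooled)
    if classifier == "svm":
        params = svm_params or {}
        model = fit_svm(Xfit[:, cols], yfit, **params)
        pred = predict(model, Xval[:, cols])
        return float(np.mean(pred != np.asarray(yval)))
    raise ValueError(f"unknown classifier {classifier!r}")


def spa_chains(
    Xtrain: np.ndarray, start_var: int, max_len: int
) -> list[int]:
    """Projection chain of column indices starting from ``start_var``.

    Each step appends the column of maximal norm after projection onto the
    orthogonal complement of the span of the chosen columns; exactly collinear
    columns (projected norm ~ 0) end the chain early.  Ties break toward the
    lowest column index, i.e. the lowest m/z on an ascending grid.
    """
    X = np.atleast_2d(np.asarray(Xtrain, dtype=float))
    n, p = X.shape
    if not 0 <= start_var < p:
        raise ValueError(f"start_var {start_var} out of range")
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    if max_len > min(n - 1, p):
        raise ValueError(f"max_len must not exceed min(n-1, p) = {min(n - 1, p)}")
    orig_norms = np.linalg.norm(X, axis=0)
    tol = 1e-10 * max(orig_norms.max(), 1.0)
    if orig_norms[start_var] <= tol:
        logger.info("spa_chains: start column %d has zero norm", start_var)
        return []
    R = X.copy()
    chain = [start_var]
    chosen = np.zeros(p, dtype=bool)
    chosen[start_var] = True
    while len(chain) < max_len:
        v = R[:, chain[-1]]
        nv = np.linalg.norm(v)
        if nv <= tol:
            logger.info("spa_chains: chain from %d terminated at length %d "
                        "(collinear column)", start_var, len(chain))
            break
        q = v / nv
        R = R - np.outer(q, q @ R)
        norms = np.linalg.norm(R, axis=0)
        norms[chosen] = -1.0
        pick = int(np.argmax(norms))  # first max -> lowest index on ties
        if norms[pick] <= tol:
            logger.info("spa_chains: chain from %d terminated at length %d "
                        "(no independent column left)", start_var, len(chain))
            break
        chain.append(pick)
        chosen[pick] = True
    return chain


def spa_all_chains(Xtrain: np.ndarray, max_len: int) -> list[list[int]]:
    """Chains from every start column (reusable across classifier couplings)."""
    p = np.atleast_2d(Xtrain).shape[1]
    return [spa_chains(Xtrain, s, max_len) for s in range(p)]


def spa_select(
    Xtrain: np.ndarray,
    ytrain: np.ndarray,
    Xval: np.ndarray,
    yval: np.ndarray,
    max_vars: int,
    classifier: str = "lda",
    mz_axis: np.ndarray | None = None,
    chains: list[list[int]] | None = None,
    svm_params: dict | None = None,
) -> SelectionResult:
    """Score every SPA chain prefix and return the global cost minimizer.

    Ties break toward fewer variables, then the lexicographically smallest
    sorted m/z tuple.  Deterministic.
    """
    X = np.atleast_2d(np.asarray(Xtrain, dtype=float))
    y = np.asarray(ytrain)
    p = X.shape[1]
    if max_vars < 1:
        raise ValueError("max_vars must be >= 1")
    axis = np.arange(p, dtype=float) if mz_axis is None else np.asarray(mz_axis, dtype=float)
    if chains is None:
        chains = spa_all_chains(X, min(max_vars, min(X.shape[0] - 1, p)))
    cache: dict[tuple[int, ...], float] = {}
    best = None  # (cost, n_vars, sorted mz tuple, chain prefix)
    for chain in chains:
        for length in range(1, len(chain) + 1):
            prefix = chain[:length]
            key = tuple(sorted(prefix))
            if key not in cache:
                cache[key] = _candidate_cost(X, y, np.atleast_2d(Xval), yval,
                                             prefix, classifier, svm_params)
            cost = cache[key]
            entry = (cost, length, tuple(axis[list(key)]), prefix)
            if best is None or entry[:3] < best[:3]:
                best = entry
    if best is None or not np.isfinite(best[0]):
        raise RuntimeError(
            "SPA selection failed: every candidate subset was singular/rejected"
        )
    cost, _, _, prefix = best
    variables = [float(axis[i]) for i in prefix]
    return SelectionResult(
        variables=variables, indices=list(prefix), cost=float(cost),
        n_runs=1, seeds=[], per_run_variables=[variables],
        per_run_costs=[float(cost)], method=f"spa-{classifier}",
    )


def _ga_single_run(X, y, Xval, yval, cfg: GAConfig, rng, classifier, svm_params,
                   cache):
    p = X.shape[1]

    def ensure_active(ch):
        if not ch.any():
            ch[rng.integers(p)] = True
            logger.info("ga_select: all-zero chromosome reinitialized")
        return ch

    def fitness(ch):
        key = tuple(np.flatnonzero(ch))
        if key not in cache:
            cache[key] = _candidate_cost(X, y, Xval, yval, list(key),
                                         classifier, svm_params)
        cost = cache[key]
        pen = cfg.penalty * max(0, len(key) - cfg.max_vars)
        return -(cost + pen), cost

    pop = rng.random((cfg.population, p)) < (cfg.init_active / p)
    pop = np.array([ensure_active(ch) for ch in pop])
    fits = np.array([fitness(ch)[0] for ch in pop])
    best_ch, best_fit = pop[int(np.argmax(fits))].copy(), float(np.max(fits))
    for _ in range(cfg.generations):
        children = [best_ch.copy()]  # elitism of 1
        while len(children) < cfg.population:
            # binary tournaments
            parents = []
            for _ in range(2):
                a, b = rng.integers(cfg.population, size=2)
                parents.append(pop[a if fits[a] >= fits[b] else b].copy())
            if rng.random() < cfg.crossover and p > 1:
                cut = int(rng.integers(1, p))
                parents[0][cut:], parents[1][cut:] = (
                    parents[1][cut:].copy(), parents[0][cut:].copy())
            for ch in parents:
                flip = rng.random(p) < cfg.mutation
                ch ^= flip
                children.append(ensure_active(ch))
        pop = np.array(children[: cfg.population])
        fits = np.array([fitness(ch)[0] for ch in pop])
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best_fit, best_ch = float(fits[gen_best]), pop[gen_best].copy()
    _, best_cost = fitness(best_ch)
    return np.flatnonzero(best_ch), best_cost, best_fit


def ga_select(
    Xtrain: np.ndarray,
    ytrain: np.ndarray,
    Xval: np.ndarray,
    yval: np.ndarray,
    cfg: GAConfig | None = None,
    seed: int = 0,
    classifier: str = "lda",
    mz_axis: np.ndarray | None = None,
    svm_params: dict | None = None,
) -> SelectionResult:
    """GA variable selection over binary chromosomes, ``cfg.n_runs`` runs.

    Fitness is the negative validation cost minus a penalty proportional to
    the number of active variables beyond ``cfg.max_vars``.  Reproducible
    given ``seed``; the reported subset is the best run's, with every run's
    subset kept in ``per_run_variables``.
    """
    cfg = cfg or GAConfig()
    X = np.atleast_2d(np.asarray(Xtrain, dtype=float))
    y = np.asarray(ytrain)
    Xv = np.atleast_2d(np.asarray(Xval, dtype=float))
    axis = (np.arange(X.shape[1], dtype=float) if mz_axis is None
            else np.asarray(mz_axis, dtype=float))
    cache: dict[tuple[int, ...], float] = {}
    seeds = [int(np.random.SeedSequence([seed, r]).generate_state(1)[0] % (2**31))
             for r in range(cfg.n_runs)]
    per_vars, per_costs, per_idx = [], [], []
    for run_seed in seeds:
        rng = np.random.default_rng(run_seed)
        idx, cost, _ = _ga_single_run(X, y, Xv, yval, cfg, rng, classifier,
                                      svm_params, cache)
        per_idx.append(idx)
        per_vars.append([float(axis[i]) for i in idx])
        per_costs.append(float(cost))
    best_run = int(np.argmin(per_costs))
    return SelectionResult(
        variables=per_vars[best_run], indices=list(map(int, per_idx[best_run])),
        cost=per_costs[best_run], n_runs=cfg.n_runs, seeds=seeds,
        per_run_variables=per_vars, per_run_costs=per_costs,
        method=f"ga-{classifier}",
    )


def pca_reduce(
    train: np.ndarray, test: np.ndarray, n_components: int = 5
) -> tuple[np.ndarray, np.ndarray, PCAModel]:
    """Fit PCA on training rows only and project both sides onto the scores."""
    model = fit_pca(train, n_components)
    return model.scores.copy(), project(model, test), model
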