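import itertools

import numpy as np
import pytest

from psiscreen.classifiers import fit_lda, predict
from psiscreen.preprocessing import preprocess_matrix
from psiscreen.sample_selection import split_train_test
from psiscreen.synthetic_data import CohortConfig, generate_cohort, make_null_cohort
from psiscreen.variable_selection import (
    GAConfig,
    ga_select,
    pca_reduce,
    risk_cost,
    spa_all_chains,
    spa_chains,
    spa_select,
)


def gram_schmidt_spa_oracle(X, start, max_len):
    """Brute-force SPA chain via explicit Gram-Schmidt on chosen columns."""
    X = np.asarray(X, float)
    p = X.shape[1]
    chain = [start]
    while len(chain) < max_len:
        basis = []
        for c in chain:
            v = X[:, c].copy()
            for b in basis:
                v -= (v @ b) * b
            nv = np.linalg.norm(v)
            if nv > 1e-10:
                basis.append(v / nv)
        best = (-1.0, None)
        for c in range(p):
            if c in chain:
                continue
            v = X[:, c].copy()
            for b in basis:
                v -= (v @ b) * b
            nv = np.linalg.norm(v)
            if nv > best[0] + 1e-12:
                best = (nv, c)
        if best[1] is None or best[0] <= 1e-10:
            break
        chain.append(best[1])
    return chain


class TestRiskCost:
    def test_point_at_own_mean_scores_zero(self):
        means = {"a": np.array([0.0, 0.0]), "b": np.array([3.0, 0.0])}
        g = risk_cost(np.array([[0.0, 0.0]]), np.array(["a"]), means, np.eye(2))
        assert g == 0.0

    def test_equidistant_point_scores_one(self):
        means = {"a": np.array([0.0]), "b": np.array([4.0])}
        g = risk_cost(np.array([[2.0]]), np.array(["a"]), means, np.eye(1))
        assert np.isclose(g, 1.0)

    def test_hand_computed_toy_value(self):
        """Two 2-D validation points, identity covariance, hand arithmetic:
        (1,0) in class a (means a=(0,0), b=(2,1)): g1 = 1 / ((1-2)^2+(0-1)^2)
        = 1/2; (3,1) in class b: g2 = (3-2)^2 / ((3-0)^2+(1-0)^2) = 1/10;
        G = (0.5 + 0.1)/2 = 0.3."""
        means = {"a": np.array([0.0, 0.0]), "b": np.array([2.0, 1.0])}
        Xval = np.array([[1.0, 0.0], [3.0, 1.0]])
        yval = np.array(["a", "b"])
        assert np.isclose(risk_cost(Xval, yval, means, np.eye(2)), 0.3)

    def test_singular_covariance_gives_infinite_cost(self):
        means = {"a": np.zeros(2), "b": np.ones(2)}
        g = risk_cost(np.array([[0.5, 0.5]]), np.array(["a"]), means,
                      np.ones((2, 2)))  # rank-1
        assert np.isinf(g)

    def test_mahalanobis_affine_invariance(self, rng):
        """G is unchanged by any invertible affine map applied to all rows."""
        X = np.vstack([rng.normal(0, 1, size=(10, 3)), rng.normal(2, 1, size=(10, 3))])
        y = np.array(["a"] * 10 + ["b"] * 10)
        Xval = rng.normal(1, 1, size=(8, 3))
        yval = np.array(["a", "b"] * 4)

        def stats(M):
            means = {c: M[y == c].mean(axis=0) for c in ("a", "b")}
            pooled = sum((M[y == c] - means[c]).T @ (M[y == c] - means[c])
                         for c in ("a", "b")) / (20 - 2)
            return means, pooled

        A = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        b = rng.normal(size=3)
        m0, p0 = stats(X)
        m1, p1 = stats(X @ A + b)
        g0 = risk_cost(Xval, yval, m0, p0)
        g1 = risk_cost(Xval @ A + b, yval, m1, p1)
        assert np.isclose(g0, g1)


class TestSpaChains:
    def test_orthogonal_columns_picked_in_norm_order(self):
        X = np.diag([3.0, 2.0, 1.0])
        assert spa_chains(X, 0, 2) == [0, 1]

    def test_collinear_column_never_selected(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=8)
        b = rng.normal(size=8)
        X = np.column_stack([a, 2 * a, b])  # column 1 collinear with 0
        chain = spa_chains(X, 0, 2)
        assert chain == [0, 2]

    def test_matches_gram_schmidt_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            n, p = int(rng.integers(4, 9)), 6
            X = rng.normal(size=(n, p))
            max_len = min(3, n - 1)
            for start in range(p):
                assert spa_chains(X, start, max_len) == \
                    gram_schmidt_spa_oracle(X, start, max_len)


class TestSpaSelect:
    @staticmethod
    def _toy_problem(rng, p=8, informative=4, delta=5.0, n=12):
        X = rng.normal(size=(2 * n, p))
        X[n:, informative] += delta
        y = np.array(["a"] * n + ["b"] * n)
        Xval = rng.normal(size=(2 * 4, p))
        Xval[4:, informative] += delta
        yval = np.array(["a"] * 4 + ["b"] * 4)
        return X, y, Xval, yval

    def test_single_informative_variable_recovered(self, rng):
        X, y, Xval, yval = self._toy_problem(rng)
        result = spa_select(X, y, Xval, yval, max_vars=3)
        assert 4 in result.indices

    def test_one_variable_problem(self, rng):
        X = np.vstack([rng.normal(0, 1, size=(6, 1)), rng.normal(3, 1, size=(6, 1))])
        y = np.array(["a"] * 6 + ["b"] * 6)
        result = spa_select(X, y, X, y, max_vars=1)
        assert result.indices == [0]

    def test_matches_exhaustive_chain_search(self, rng):
        """Oracle: enumerate every SPA-reachable prefix and pick the best by
        the same (cost, size, lexicographic) rule."""
        X, y, Xval, yval = self._toy_problem(rng, p=8)
        max_vars = 3
        result = spa_select(X, y, Xval, yval, max_vars=max_vars)
        from psiscreen.variable_selection import _candidate_cost
        best = None
        for start in range(8):
            chain = gram_schmidt_spa_oracle(X, start, max_vars)
            for L in range(1, len(chain) + 1):
                key = tuple(sorted(chain[:L]))
                cost = _candidate_cost(X, y, Xval, yval, list(chain[:L]), "lda", None)
                entry = (cost, L, key)
                if best is None or entry < best:
                    best = entry
        assert tuple(sorted(result.indices)) == best[2]
        assert np.isclose(result.cost, best[0])

    def test_svm_coupling_uses_error_rate(self, rng):
        X, y, Xval, yval = self._toy_problem(rng)
        result = spa_select(X, y, Xval, yval, max_vars=2, classifier="svm")
        assert 0.0 <= result.cost <= 1.0
        assert 4 in result.indices


class TestGaSelect:
    @pytest.fixture(scope="class")
    def strong_small(self):
        """Reduced-grid strong cohort split into fit/validation."""
        cfg = CohortConfig(mz_min=50.0, mz_max=250.0, seed=21,
                           shared_peaks=((60.0, 80.0, 0.25), (95.0, 150.0, 0.25),
                                         (130.0, 50.0, 0.25), (200.0, 120.0, 0.25)))
        m, truth = generate_cohort(cfg)
        pm = preprocess_matrix(m)
        split = split_train_test(pm, 0.7)
        tr = pm.subset(split.train_idx)
        carve = split_train_test(tr, 0.7)
        fit, val = tr.subset(carve.train_idx), tr.subset(carve.test_idx)
        return fit, val, truth

    def test_fixed_seed_is_deterministic(self, strong_small):
        fit, val, _ = strong_small
        cfg = GAConfig(population=10, generations=5, n_runs=2)
        r1 = ga_select(fit.X, fit.labels(), val.X, val.labels(), cfg, seed=3,
                       mz_axis=fit.mz_axis)
        r2 = ga_select(fit.X, fit.labels(), val.X, val.labels(), cfg, seed=3,
                       mz_axis=fit.mz_axis)
        assert r1.per_run_variables == r2.per_run_variables
        assert r1.per_run_costs == r2.per_run_costs

    def test_planted_variable_fitness_dominates_noise_singletons(self, strong_small):
        from psiscreen.variable_selection import _candidate_cost
        fit, val, truth = strong_small
        planted_cols = [fit.column_index(mz) for mz in truth.discriminative_mz]
        best_planted = min(
            _candidate_cost(fit.X, fit.labels(), val.X, val.labels(), [c],
                            "lda", None) for c in planted_cols)
        rng = np.random.default_rng(0)
        noise_cols = [c for c in range(fit.n_variables) if c not in planted_cols]
        sample = rng.choice(noise_cols, size=30, replace=False)
        for c in sample:
            g = _candidate_cost(fit.X, fit.labels(), val.X, val.labels(),
                                [int(c)], "lda", None)
            assert best_planted <= g

    def test_stochastic_recovery_across_cohorts(self):
        """Strong planted signal is found in >= 2 of 3 GA runs for most cohorts."""
        wins = 0
        n_cohorts = 10
        for seed in range(n_cohorts):
            cfg = CohortConfig(mz_min=50.0, mz_max=250.0, seed=100 + seed,
                               shared_peaks=((60.0, 80.0, 0.25),
                                             (95.0, 150.0, 0.25),
                                             (130.0, 50.0, 0.25),
                                             (200.0, 120.0, 0.25)))
            m, truth = generate_cohort(cfg)
            pm = preprocess_matrix(m)
            split = split_train_test(pm, 0.7)
            tr = pm.subset(split.train_idx)
            carve = split_train_test(tr, 0.7)
            fit, val = tr.subset(carve.train_idx), tr.subset(carve.test_idx)
            sel = ga_select(fit.X, fit.labels(), val.X, val.labels(),
                            GAConfig(population=20, generations=30), seed=seed,
                            mz_axis=fit.mz_axis)
            hits = sum(1 for run in sel.per_run_variables
                       if any(mz in run for mz in truth.discriminative_mz))
            wins += hits >= 2
        assert wins >= 6

    def test_reports_three_runs_and_union(self, strong_small):
        fit, val, _ = strong_small
        sel = ga_select(fit.X, fit.labels(), val.X, val.labels(),
                        GAConfig(population=10, generations=5), seed=1,
                        mz_axis=fit.mz_axis)
        assert sel.n_runs == 3 and len(sel.per_run_variables) == 3
        assert len(sel.seeds) == 3
        assert set(sel.variables) <= set(sel.union_variables)


class TestNullScatter:
    def test_spa_selection_scatters_on_null_cohorts(self):
        """No variable should recur in > 60% of null cohorts."""
        from collections import Counter
        counts = Counter()
        n_cohorts = 50
        for seed in range(n_cohorts):
            cfg = CohortConfig(mz_min=50.0, mz_max=200.0, seed=300 + seed,
                               shared_peaks=((60.0, 80.0, 0.25),
                                             (95.0, 150.0, 0.25),
                                             (130.0, 50.0, 0.25)))
            m, _ = make_null_cohort(cfg)
            pm = preprocess_matrix(m)
            split = split_train_test(pm, 0.7)
            tr = pm.subset(split.train_idx)
            carve = split_train_test(tr, 0.7)
            fit, val = tr.subset(carve.train_idx), tr.subset(carve.test_idx)
            sel = spa_select(fit.X, fit.labels(), val.X, val.labels(), max_vars=3,
                             mz_axis=fit.mz_axis)
            counts.update(set(sel.variables))
        assert max(counts.values()) <= 0.6 * n_cohorts


class TestPcaReduce:
    def test_five_components_give_five_columns(self, rng):
        train, test = rng.normal(size=(20, 40)), rng.normal(size=(8, 40))
        tr, te, model = pca_reduce(train, test, 5)
        assert tr.shape == (20, 5) and te.shape == (8, 5)
        assert model.n_components == 5

    def test_full_rank_scores_equal_classification(self, rng):
        """LDA on full-rank scores equals LDA on the raw variables
        (rotation invariance of Mahalanobis distances)."""
        train = np.vstack([rng.normal(0, 1, size=(10, 6)),
                           rng.normal(1.5, 1, size=(10, 6))])
        test = rng.normal(0.7, 1.2, size=(12, 6))
        y = np.array(["a"] * 10 + ["b"] * 10)
        tr, te, _ = pca_reduce(train, test, 6)
        p_scores = predict(fit_lda(tr, y), te)
        p_raw = predict(fit_lda(train, y), test)
        assert np.array_equal(p_scores, p_raw)

    def test_rank_one_single_component_reconstructs(self, rng):
        t = rng.normal(size=10)
        train = np.outer(t, [1.0, -2.0, 0.5])
        tr, te, model = pca_reduce(train, train, 1)
        from psiscreen.pca import inverse_project
        assert np.allclose(inverse_project(model, tr), train, atol=1e-10)
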