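import numpy as np
import pytest

from psiscreen.classifiers import (
    covariance_similarity,
    decision_scores,
    fit_lda,
    fit_qda,
    fit_svm,
    model_from_json,
    model_to_json,
    predict,
)


def brute_force_discriminant(X, y, Xnew, kind):
    """Independent LDA/QDA by explicit means, covariances and solves."""
    X, Xnew = np.asarray(X, float), np.atleast_2d(np.asarray(Xnew, float))
    classes = sorted(set(y))
    n, K = len(y), len(classes)
    stats = {}
    for c in classes:
        rows = X[np.asarray(y) == c]
        stats[c] = (rows.mean(axis=0), rows - rows.mean(axis=0), rows.shape[0])
    pooled = sum(cc.T @ cc for _, cc, _ in stats.values()) / (n - K)
    out = []
    for x in Xnew:
        best = None
        for c in classes:
            mu, cc, nk = stats[c]
            S = pooled if kind == "lda" else cc.T @ cc / (nk - 1)
            d2 = float((x - mu) @ np.linalg.solve(S, x - mu))
            score = d2 - 2 * np.log(nk / n)
            if kind == "qda":
                score += float(np.linalg.slogdet(S)[1])
            if best is None or score < best[0]:
                best = (score, c)
        out.append(best[1])
    return np.array(out)


class TestLda:
    def test_class_mean_predicted_as_own_class(self, rng):
        X = np.vstack([rng.normal(0, 1, size=(10, 2)), rng.normal(5, 1, size=(10, 2))])
        y = np.array(["a"] * 10 + ["b"] * 10)
        model = fit_lda(X, y, priors="equal")
        mu_b = X[10:].mean(axis=0)
        assert predict(model, mu_b[None, :])[0] == "b"

    def test_1d_boundary_at_midpoint(self):
        rng = np.random.default_rng(3)
        X = np.concatenate([rng.normal(0, 1, 2000), rng.normal(4, 1, 2000)])[:, None]
        y = np.array(["lo"] * 2000 + ["hi"] * 2000)
        model = fit_lda(X, y, priors="equal")
        eps = 0.15  # sampled means wobble the boundary slightly
        assert predict(model, [[2 - eps]])[0] == "lo"
        assert predict(model, [[2 + eps]])[0] == "hi"

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            d = int(rng.integers(1, 4))
            n = int(rng.integers(4, 9))
            X = np.vstack([rng.normal(0, 1, size=(n, d)),
                           rng.normal(rng.uniform(0, 3), 1, size=(n, d))])
            y = np.array(["a"] * n + ["b"] * n)
            Xnew = rng.normal(1, 2, size=(6, d))
            model = fit_lda(X, y)
            assert np.array_equal(predict(model, Xnew),
                                  brute_force_discriminant(X, y, Xnew, "lda"))

    def test_affine_equivariance(self, rng):
        X = np.vstack([rng.normal(0, 1, size=(15, 3)),
                       rng.normal(2, 1, size=(15, 3))])
        y = np.array(["a"] * 15 + ["b"] * 15)
        Xnew = rng.normal(1, 1.5, size=(10, 3))
        A = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        b = rng.normal(size=3)
        p0 = predict(fit_lda(X, y), Xnew)
        p1 = predict(fit_lda(X @ A + b, y), Xnew @ A + b)
        assert np.array_equal(p0, p1)


class TestQda:
    def test_reduces_to_lda_under_equal_covariances(self, rng):
        base = rng.normal(size=(12, 3))
        X = np.vstack([base, base + np.array([3.0, -1.0, 2.0])])
        y = np.array(["a"] * 12 + ["b"] * 12)
        Xnew = rng.normal(1, 2, size=(20, 3))
        assert np.array_equal(predict(fit_qda(X, y), Xnew),
                              predict(fit_lda(X, y), Xnew))

    def test_1d_unequal_variance_threshold(self):
        """Closed-form oracle: N(0,1) vs N(0,9), equal priors.

        Scores tie where x^2 (1 - 1/9) = ln 9, i.e. |x| = 1.5734; inside the
        tighter class wins, outside the wider one.
        """
        rng = np.random.default_rng(5)
        X = np.concatenate([rng.normal(0, 1, 40000), rng.normal(0, 3, 40000)])[:, None]
        y = np.array(["tight"] * 40000 + ["wide"] * 40000)
        model = fit_qda(X, y, priors="equal")
        thresh = np.sqrt(np.log(9.0) / (1 - 1 / 9))
        eps = 0.05
        assert predict(model, [[thresh - eps]])[0] == "tight"
        assert predict(model, [[thresh + eps]])[0] == "wide"
        assert predict(model, [[-thresh - eps]])[0] == "wide"

    def test_class_mean_with_equal_determinants(self, rng):
        base = rng.normal(size=(10, 2))
        X = np.vstack([base, base + 4.0])
        y = np.array(["a"] * 10 + ["b"] * 10)
        model = fit_qda(X, y, priors="equal")
        assert predict(model, X[:10].mean(axis=0)[None, :])[0] == "a"

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            d = int(rng.integers(1, 3))
            n = int(rng.integers(d + 2, 10))
            X = np.vstack([rng.normal(0, 1, size=(n, d)),
                           rng.normal(1.0, 2.0, size=(n, d))])
            y = np.array(["a"] * n + ["b"] * n)
            Xnew = rng.normal(0.5, 2, size=(6, d))
            assert np.array_equal(predict(fit_qda(X, y), Xnew),
                                  brute_force_discriminant(X, y, Xnew, "qda"))

    def test_covariance_similarity_diagnostic(self, rng):
        base = rng.normal(size=(20, 2))
        X_same = np.vstack([base, base + 1.0])
        y = np.array(["a"] * 20 + ["b"] * 20)
        assert covariance_similarity(fit_qda(X_same, y)) < 1e-10
        X_diff = np.vstack([base, 5 * base + 1.0])
        assert covariance_similarity(fit_qda(X_diff, y)) > 0.5


class TestSvm:
    def test_linearly_separable_degree_one(self):
        X = np.array([[0.0, 0], [0, 1], [4, 0], [4, 1]])
        y = np.array(["a", "a", "b", "b"])
        model = fit_svm(X, y, degree=1, C=100.0)
        assert np.array_equal(predict(model, X), y)

    def test_xor_with_degree_two(self):
        X = np.array([[1.0, 1], [-1, -1], [1, -1], [-1, 1]])
        y = np.array(["a", "a", "b", "b"])
        model = fit_svm(X, y, degree=2, C=1e6)
        assert np.array_equal(predict(model, X), y)

    def test_duplicating_points_preserves_decision(self, rng):
        X = np.vstack([rng.normal(0, 1, size=(10, 2)), rng.normal(6, 1, size=(10, 2))])
        y = np.array(["a"] * 10 + ["b"] * 10)
        grid = rng.normal(3, 3, size=(30, 2))
        m1 = fit_svm(X, y, C=1e6)
        m2 = fit_svm(np.vstack([X, X]), np.concatenate([y, y]), C=1e6)
        assert np.array_equal(predict(m1, grid), predict(m2, grid))

    def test_support_vectors_in_both_classes(self, rng):
        X = np.vstack([rng.normal(0, 1, size=(8, 2)), rng.normal(3, 1, size=(8, 2))])
        y = np.array(["a"] * 8 + ["b"] * 8)
        model = fit_svm(X, y)
        duals = model.dual_coef
        assert (duals > 0).any() and (duals < 0).any()


class TestPredict:
    def test_empty_input_gives_empty_labels(self, rng):
        X = np.vstack([rng.normal(0, 1, size=(5, 2)), rng.normal(3, 1, size=(5, 2))])
        y = np.array(["a"] * 5 + ["b"] * 5)
        model = fit_lda(X, y)
        labels = predict(model, np.empty((0, 2)))
        assert labels.size == 0

    def test_labels_agree_with_score_argmin(self, rng):
        X = np.vstack([rng.normal(0, 1, size=(8, 3)), rng.normal(1, 2, size=(8, 3))])
        y = np.array(["a"] * 8 + ["b"] * 8)
        Xnew = rng.normal(size=(20, 3))
        for model in (fit_lda(X, y), fit_qda(X, y), fit_svm(X, y)):
            labels, scores = predict(model, Xnew, return_scores=True)
            assert np.array_equal(
                labels, np.asarray(model.classes)[np.argmin(scores, axis=1)])

    def test_column_mismatch_rejected(self, rng):
        X = np.vstack([rng.normal(0, 1, size=(5, 3)), rng.normal(3, 1, size=(5, 3))])
        y = np.array(["a"] * 5 + ["b"] * 5)
        with pytest.raises(ValueError):
            predict(fit_lda(X, y), rng.normal(size=(2, 4)))


class TestSerialization:
    def test_json_roundtrip_preserves_predictions(self, rng):
        X = np.vstack([rng.normal(0, 1, size=(10, 3)), rng.normal(2, 1.5, size=(10, 3))])
        y = np.array(["a"] * 10 + ["b"] * 10)
        Xnew = rng.normal(1, 2, size=(25, 3))
        for fit in (fit_lda, fit_qda, fit_svm):
            model = fit(X, y)
            clone = model_from_json(model_to_json(model))
            assert np.array_equal(predict(model, Xnew), predict(clone, Xnew))
            assert np.allclose(decision_scores(model, Xnew),
                               decision_scores(clone, Xnew))


class TestRegularization:
    def test_singular_pooled_covariance_is_ridged_not_fatal(self, rng):
        X = np.vstack([rng.normal(0, 1, size=(4, 6)), rng.normal(2, 1, size=(4, 6))])
        y = np.array(["a"] * 4 + ["b"] * 4)  # n - K = 6 = p: singular-ish
        model = fit_lda(X, y)
        assert model.ridge >= 0.0
        predict(model, rng.normal(size=(3, 6)))  # must not raise
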