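"""Supervised K-fold LDA assignment framework."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from soletrace.assignment import (
    assignment_matrix,
    lda_posterior,
    lda_train,
    make_folds,
    pca_preprocess,
    run_assignment,
)


class TestMakeFolds:
    def test_study_design_fold_sizes(self):
        labels = np.array(["SW"] * 47 + ["NE"] * 31 + ["UK"] * 42)
        plan = make_folds(labels, K=3, seed=0)
        sw_sizes = sorted(
            np.bincount(plan.fold_ids[labels == "SW"], minlength=3), reverse=True
        )
        assert sw_sizes == [16, 16, 15]
        ne_sizes = sorted(np.bincount(plan.fold_ids[labels == "NE"]), reverse=True)
        assert ne_sizes == [11, 10, 10]
        # every fold contains every subunit
        for f in range(3):
            assert set(labels[plan.fold_ids == f]) == {"SW", "NE", "UK"}

    def test_k_equal_group_size_gives_leave_one_out(self):
        labels = np.array(["A"] * 5 + ["B"] * 5)
        plan = make_folds(labels, K=5, seed=1)
        for f in range(5):
            sel = plan.fold_ids == f
            assert (labels[sel] == "A").sum() == 1
            assert (labels[sel] == "B").sum() == 1

    def test_small_subunit_rejected_by_name(self):
        labels = np.array(["SW"] * 10 + ["NE"] * 2)
        with pytest.raises(ValueError, match="NE"):
            make_folds(labels, K=3, seed=0)

    def test_different_seeds_different_partitions_same_profile(self):
        labels = np.array(["A"] * 12 + ["B"] * 9)
        p1 = make_folds(labels, K=3, seed=1)
        p2 = make_folds(labels, K=3, seed=2)
        assert not np.array_equal(p1.fold_ids, p2.fold_ids)
        assert sorted(np.bincount(p1.fold_ids)) == sorted(np.bincount(p2.fold_ids))


class TestPcaPreprocess:
    def test_loadings_independent_of_test_rows(self):
        rng = np.random.default_rng(0)
        train = rng.normal(size=(40, 10))
        t1, s1, pca1 = pca_preprocess(train, rng.normal(size=(5, 10)))
        t2, s2, pca2 = pca_preprocess(train, rng.normal(size=(8, 10)) * 100)
        np.testing.assert_allclose(pca1.components_, pca2.components_, atol=1e-12)
        np.testing.assert_allclose(t1, t2, atol=1e-12)

    def test_rank2_data_keeps_at_most_two(self):
        rng = np.random.default_rng(1)
        basis = rng.normal(size=(2, 8))
        X = rng.normal(size=(30, 2)) @ basis
        scores, _, pca = pca_preprocess(X, var_threshold=0.999)
        assert scores.shape[1] <= 2

    def test_scores_match_eigendecomposition(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 6))
        scores, _, pca = pca_preprocess(X, var_threshold=0.95)
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc)
        order = np.argsort(evals)[::-1]
        ref = Xc @ evecs[:, order[: scores.shape[1]]]
        for j in range(scores.shape[1]):
            sign = np.sign(scores[:, j] @ ref[:, j])
            np.testing.assert_allclose(scores[:, j], sign * ref[:, j], atol=1e-8)

    def test_empty_training_rejected(self):
        with pytest.raises(ValueError):
            pca_preprocess(np.empty((0, 4)))


class TestLda:
    def _two_classes(self, rng, gap=10.0, n=30):
        X = np.vstack(
            [rng.normal(0, 1, size=(n, 3)), rng.normal(gap, 1, size=(n, 3))]
        )
        y = np.array(["a"] * n + ["b"] * n)
        return X, y

    def test_far_classes_boundary_at_midpoint(self):
        rng = np.random.default_rng(3)
        X, y = self._two_classes(rng)
        model = lda_train(X, y, priors="uniform")
        mid = (model.means[0] + model.means[1]) / 2.0
        post = lda_posterior(model, mid[None, :])
        np.testing.assert_allclose(post, [[0.5, 0.5]], atol=1e-8)

    def test_identical_means_return_priors(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(60, 3))
        y = np.array(["a"] * 40 + ["b"] * 20)
        model = lda_train(X, y, priors="proportional")
        model.means[1] = model.means[0]
        post = lda_posterior(model, rng.normal(size=(5, 3)))
        np.testing.assert_allclose(post, np.tile([2 / 3, 1 / 3], (5, 1)), atol=1e-9)

    def test_posterior_matches_bruteforce_gaussian_bayes(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(90, 4)) + np.repeat(
            np.array([[0.0], [1.0], [2.5]]), 30, axis=0
        )
        y = np.repeat(["a", "b", "c"], 30)
        model = lda_train(X, y)
        query = rng.normal(1.0, 1.0, size=(20, 4))
        got = lda_posterior(model, query)
        # oracle: scipy multivariate normal densities with the pooled covariance
        pooled = np.zeros((4, 4))
        for i, c in enumerate(["a", "b", "c"]):
            d = X[y == c] - X[y == c].mean(axis=0)
            pooled += d.T @ d
        pooled /= len(X) - 3
        priors = np.array([1 / 3, 1 / 3, 1 / 3])
        dens = np.stack(
            [
                priors[i]
                * multivariate_normal.pdf(query, mean=X[y == c].mean(axis=0), cov=pooled)
                for i, c in enumerate(["a", "b", "c"])
            ],
            axis=1,
        )
        ref = dens / dens.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(got, ref, atol=1e-10)

    def test_matches_sklearn_lda(self):
        rng = np.random.default_rng(6)
        X, y = self._two_classes(rng, gap=2.0)
        model = lda_train(X, y)
        got = lda_posterior(model, X)
        sk = LinearDiscriminantAnalysis(solver="svd").fit(X, y)
        np.testing.assert_allclose(got, sk.predict_proba(X), atol=1e-8)

    def test_translation_invariance_and_duplicates(self):
        rng = np.random.default_rng(7)
        X, y = self._two_classes(rng, gap=3.0)
        m1 = lda_train(X, y)
        m2 = lda_train(X + 57.0, y)
        q = rng.normal(size=(4, 3))
        np.testing.assert_allclose(
            lda_posterior(m1, q), lda_posterior(m2, q + 57.0), atol=1e-8
        )
        dup = np.vstack([q[0], q[0]])
        post = lda_posterior(m1, dup)
        np.testing.assert_allclose(post[0], post[1], atol=1e-15)

    def test_argmax_equals_prior_corrected_mahalanobis(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(80, 3)) + np.repeat(np.array([[0.0], [1.5]]), 40, axis=0)
        y = np.repeat(["a", "b"], 40)
        model = lda_train(X, y)
        q = rng.normal(0.7, 1.0, size=(25, 3))
        post = lda_posterior(model, q)
        diffs = q[:, None, :] - model.means[None, :, :]
        maha = np.einsum("nkp,pq,nkq->nk", diffs, model.cov_inv, diffs)
        score = model.log_priors - 0.5 * maha
        np.testing.assert_array_equal(post.argmax(axis=1), score.argmax(axis=1))

    def test_underdetermined_covariance_rejected(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(6, 10))
        y = np.array(["a", "a", "a", "b", "b", "b"])
        with pytest.raises(ValueError):
            lda_train(X, y)


class TestRunAssignment:
    def test_pure_noise_balanced_is_chance_level(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(120, 15))
        labels = np.repeat(["SW", "NE", "UK"], 40)
        res = run_assignment(X, labels, K=3, seed=0, n_repeats=10)
        se = np.sqrt((1 / 3) * (2 / 3) / 120)
        assert abs(res.mean_self_assignment - 1 / 3) < 3 * se

    def test_pure_noise_unbalanced_attracts_to_largest_class(self):
        rng = np.random.default_rng(11)
        labels = np.array(["SW"] * 128 + ["NE"] * 30 + ["UK"] * 80)
        X = rng.normal(size=(len(labels), 15))
        res = run_assignment(X, labels, K=3, seed=1, n_repeats=10)
        m = res.matrix_mean
        for origin in ("SW", "NE", "UK"):
            assert m.loc[origin, "SW"] == m.loc[origin].max()

    def test_separated_clusters_fully_self_assigned(self):
        rng = np.random.default_rng(12)
        X = np.vstack([rng.normal(i * 30, 1, size=(15, 4)) for i in range(3)])
        labels = np.repeat(["SW", "NE", "UK"], 15)
        res = run_assignment(X, labels, K=3, seed=2, n_repeats=3)
        assert res.mean_self_assignment == 1.0
        assert res.matrix_sd.values.max() == 0.0

    def test_each_individual_predicted_once_per_pass(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(30, 5))
        labels = np.repeat(["SW", "NE", "UK"], 10)
        res = run_assignment(X, labels, K=3, seed=3, n_repeats=2)
        counts = res.posteriors.groupby(["repeat", "id"]).size()
        assert (counts == 1).all()

    def test_matrix_rows_sum_to_one(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(60, 5))
        labels = np.repeat(["SW", "NE", "UK"], 20)
        res = run_assignment(X, labels, K=3, seed=4, n_repeats=5)
        np.testing.assert_allclose(res.matrix_mean.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(
            res.posteriors[[f"P({c})" for c in res.classes]].sum(axis=1), 1.0, atol=1e-9
        )

    def test_residualize_preprocess_requires_design(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(30, 4))
        labels = np.repeat(["SW", "NE", "UK"], 10)
        with pytest.raises(ValueError):
            run_assignment(X, labels, preprocess="residualize")


class TestAssignmentMatrix:
    def test_two_test_cell_mean_and_sd_arithmetic(self):
        # two tests where the SW->SW fraction is 0.6 then 0.8
        rows = []
        for rep, accs in enumerate([(3, 5), (4, 5)]):  # 0.6 and 0.8
            hit, n = accs
            for i in range(n):
                rows.append(
                    {
                        "id": f"i{i}",
                        "subunit": "SW",
                        "repeat": rep,
                        "fold": 0,
                        "predicted": "SW" if i < hit else "NE",
                        "P(SW)": 1.0,
                        "P(NE)": 0.0,
                    }
                )
        from soletrace.assignment import _matrices_from_posteriors

        mean, sd = _matrices_from_posteriors(pd.DataFrame(rows), ["SW", "NE"])
        assert mean.loc["SW", "SW"] == pytest.approx(0.7)
        assert sd.loc["SW", "SW"] == pytest.approx(np.sqrt(0.02), rel=1e-9)  # 0.1414

    def test_matches_bruteforce_tally(self):
        rng = np.random.default_rng(16)
        X = rng.normal(size=(45, 6))
        labels = np.repeat(["SW", "NE", "UK"], 15)
        res = run_assignment(X, labels, K=3, seed=5, n_repeats=4)
        df = res.posteriors
        fracs = []
        for (_, _), grp in df.groupby(["repeat", "fold"]):
            sub = grp[grp["subunit"] == "SW"]
            fracs.append((sub["predicted"] == "SW").mean())
        assert res.matrix_mean.loc["SW", "SW"] == pytest.approx(np.mean(fracs))

    def test_pooling_results_requires_consistent_classes(self):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(30, 4))
        r1 = run_assignment(X, np.repeat(["SW", "NE", "UK"], 10), K=3, seed=6)
        r2 = run_assignment(X, np.repeat(["A", "B", "C"], 10), K=3, seed=6)
        with pytest.raises(ValueError):
            assignment_matrix([r1, r2])
        mean, sd = assignment_matrix([r1, r1])
        np.testing.assert_allclose(mean.sum(axis=1), 1.0, atol=1e-9)
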