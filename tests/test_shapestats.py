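"""RDA with permutation tests, Type III ANOVA, Tukey HSD, residualization."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf
from scipy import stats

from soletrace.shapestats import (
    anova_type3,
    fit_index_model,
    rda_fit,
    rda_permutation_test,
    residualize,
    tukey_hsd,
)


def make_design(n, rng, years=(2016, 2017, 2018)):
    return pd.DataFrame(
        {
            "subunit": rng.choice(["SW", "NE", "UK"], n),
            "length_cm": rng.uniform(25, 40, n),
            "side": rng.choice(["L", "R"], n),
            "sex": rng.choice(["F", "M"], n),
            "year": rng.choice(years, n),
        }
    )


class TestRdaFit:
    def test_single_response_single_predictor_reduces_to_ols_r2(self):
        rng = np.random.default_rng(0)
        n = 80
        design = make_design(n, rng)
        y = 0.5 * design["length_cm"].to_numpy() + rng.normal(size=n)
        m = rda_fit(y, design, terms=("Length",))
        r2 = m.constrained_inertia / m.total_inertia
        slope, intercept, r, *_ = stats.linregress(design["length_cm"], y)
        assert r2 == pytest.approx(r**2, abs=1e-12)

    def test_inertia_partition_is_exact(self):
        rng = np.random.default_rng(1)
        design = make_design(60, rng)
        Y = rng.normal(size=(60, 4))
        m = rda_fit(Y, design)
        assert m.total_inertia == pytest.approx(
            m.constrained_inertia + m.residual_inertia, rel=1e-12
        )

    def test_subunit_mean_structure_gives_zero_residual(self):
        rng = np.random.default_rng(2)
        design = make_design(50, rng)
        means = {"SW": 1.0, "NE": -2.0, "UK": 3.0}
        Y = np.array([[means[s]] for s in design["subunit"]])
        m = rda_fit(Y, design, terms=("Subunit",))
        assert m.residual_inertia == pytest.approx(0.0, abs=1e-18)

    def test_rank_deficient_design_rejected(self):
        rng = np.random.default_rng(3)
        design = make_design(40, rng)
        design["side"] = design["sex"].map({"F": "L", "M": "R"})  # aliased
        with pytest.raises(ValueError, match="aliased|rank"):
            rda_fit(rng.normal(size=(40, 2)), design)


class TestRdaPermutation:
    def test_reproducible_and_zero_perm_rejected(self):
        rng = np.random.default_rng(4)
        design = make_design(50, rng)
        m = rda_fit(rng.normal(size=(50, 3)), design)
        t1 = rda_permutation_test(m, n_perm=99, seed=5)
        t2 = rda_permutation_test(m, n_perm=99, seed=5)
        pd.testing.assert_frame_equal(t1, t2)
        with pytest.raises(ValueError):
            rda_permutation_test(m, n_perm=0)

    def test_injected_subunit_shift_detected(self):
        hits = 0
        reps = 15
        for rep in range(reps):
            rng = np.random.default_rng(100 + rep)
            design = make_design(90, rng)
            Y = rng.normal(size=(90, 5))
            Y[:, 0] += (design["subunit"] == "SW").to_numpy() * 1.5
            m = rda_fit(Y, design)
            tab = rda_permutation_test(m, n_perm=199, seed=rep)
            hits += float(tab.loc[tab.term == "Subunit", "p"].iloc[0]) <= 0.05
        assert hits >= int(0.9 * reps)


class TestIndexModels:
    def test_exact_recovery_with_zero_noise(self):
        rng = np.random.default_rng(6)
        design = make_design(100, rng)
        y = (
            2.0
            + 0.3 * design["length_cm"].to_numpy()
            + 1.5 * (design["subunit"] == "SW").to_numpy()
            - 0.7 * (design["sex"] == "M").to_numpy()
        )
        fit = fit_index_model(y, design)
        np.testing.assert_allclose(fit.resid, 0.0, atol=1e-8)

    def test_coefficients_match_normal_equations(self):
        rng = np.random.default_rng(7)
        design = make_design(80, rng)
        y = rng.normal(size=80)
        fit = fit_index_model(y, design)
        X = fit.model.exog
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(fit.params, beta, atol=1e-8)

    def test_intercept_only_fits_the_mean(self):
        rng = np.random.default_rng(8)
        design = make_design(30, rng)
        y = rng.normal(size=30)
        frame = design.copy()
        frame["si"] = y
        fit = smf.ols("si ~ 1", data=frame).fit()
        np.testing.assert_allclose(fit.fittedvalues, y.mean(), atol=1e-12)

    def test_single_level_factor_rejected(self):
        rng = np.random.default_rng(9)
        design = make_design(40, rng)
        design["sex"] = "F"
        with pytest.raises(ValueError):
            fit_index_model(rng.normal(size=40), design)


class TestAnovaType3:
    def test_balanced_one_factor_equals_classical_oneway(self):
        rng = np.random.default_rng(10)
        groups = np.repeat(["SW", "NE", "UK"], 20)
        y = rng.normal(size=60) + np.repeat([0.0, 0.5, 1.0], 20)
        frame = pd.DataFrame({"Subunit": groups, "si": y})
        fit = smf.ols("si ~ C(Subunit, Sum)", data=frame).fit()
        table = anova_type3(fit)
        f_ref, p_ref = stats.f_oneway(y[:20], y[20:40], y[40:])
        row = table[table.term == "Subunit"].iloc[0]
        assert row.F == pytest.approx(f_ref, rel=1e-10)
        assert row.p == pytest.approx(p_ref, rel=1e-10)

    def test_unbalanced_two_factor_matches_full_vs_reduced_bruteforce(self):
        rng = np.random.default_rng(11)
        n = 73
        A = rng.choice(["SW", "NE", "UK"], n, p=[0.5, 0.3, 0.2])
        B = rng.choice(["F", "M"], n, p=[0.6, 0.4])
        y = rng.normal(size=n) + (A == "SW") * 0.8 + (B == "M") * 0.4
        frame = pd.DataFrame({"Subunit": A, "Sex": B, "si": y})
        fit = smf.ols("si ~ C(Subunit, Sum) + C(Sex, Sum)", data=frame).fit()
        table = anova_type3(fit)

        def sum_code(values, levels):
            # sum-to-zero contrasts: last level = -1 row
            cols = []
            for lv in levels[:-1]:
                col = np.where(values == lv, 1.0, 0.0)
                col[values == levels[-1]] = -1.0
                cols.append(col)
            return np.column_stack(cols)

        lev_a = sorted(set(A))
        lev_b = sorted(set(B))
        Xa = sum_code(A, lev_a)
        Xb = sum_code(B, lev_b)
        ones = np.ones((n, 1))
        X_full = np.hstack([ones, Xa, Xb])
        X_red = np.hstack([ones, Xb])

        def rss(X):
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            return ((y - X @ beta) ** 2).sum()

        df_term = Xa.shape[1]
        df_res = n - X_full.shape[1]
        F_ref = ((rss(X_red) - rss(X_full)) / df_term) / (rss(X_full) / df_res)
        row = table[table.term == "Subunit"].iloc[0]
        assert row.F == pytest.approx(F_ref, rel=1e-8)

    def test_treatment_coding_refused(self):
        rng = np.random.default_rng(12)
        frame = pd.DataFrame(
            {"Subunit": rng.choice(["SW", "NE"], 30), "si": rng.normal(size=30)}
        )
        fit = smf.ols("si ~ C(Subunit)", data=frame).fit()
        with pytest.raises(ValueError, match="sum-to-zero"):
            anova_type3(fit)


class TestTukey:
    def test_two_groups_equals_pooled_t_through_studentized_range(self):
        rng = np.random.default_rng(13)
        n1, n2 = 14, 21
        y = np.concatenate([rng.normal(0, 1, n1), rng.normal(0.8, 1, n2)])
        groups = np.array(["SW"] * n1 + ["NE"] * n2)
        frame = pd.DataFrame({"Subunit": groups, "si": y})
        fit = smf.ols("si ~ C(Subunit, Sum)", data=frame).fit()
        table = tukey_hsd(fit, "Subunit")
        t_stat, _ = stats.ttest_ind(y[:n1], y[n1:], equal_var=True)[:2]
        # HSD with harmonic-mean n: q = |t| * sqrt(2) only for equal n; with
        # harmonic mean the mapping uses 2/n_h = mean of 1/n_i
        n_h = 2.0 / (1.0 / n1 + 1.0 / n2)
        q_ref = abs(y[:n1].mean() - y[n1:].mean()) / np.sqrt(fit.mse_resid / n_h)
        assert q_ref == pytest.approx(abs(t_stat) * np.sqrt(2), rel=1e-10)
        p_ref = stats.studentized_range.sf(q_ref, 2, n1 + n2 - 2)
        assert table["p"].iloc[0] == pytest.approx(p_ref, rel=1e-9)

    def test_identical_means_share_a_letter(self):
        rng = np.random.default_rng(14)
        y = rng.normal(size=90) * 0.01
        groups = np.repeat(["SW", "NE", "UK"], 30)
        frame = pd.DataFrame({"Subunit": groups, "si": y})
        fit = smf.ols("si ~ C(Subunit, Sum)", data=frame).fit()
        table = tukey_hsd(fit, "Subunit")
        letters = table.attrs["letters"]
        assert len(set(letters.values())) == 1

    def test_shifted_group_separates_in_most_replicates(self):
        seps = 0
        reps = 10
        for rep in range(reps):
            rng = np.random.default_rng(200 + rep)
            y = np.concatenate(
                [rng.normal(1.2, 1, 40), rng.normal(0, 1, 40), rng.normal(0, 1, 40)]
            )
            groups = np.repeat(["SW", "NE", "UK"], 40)
            frame = pd.DataFrame({"Subunit": groups, "si": y})
            fit = smf.ols("si ~ C(Subunit, Sum)", data=frame).fit()
            letters = tukey_hsd(fit, "Subunit").attrs["letters"]
            seps += set(letters["SW"]).isdisjoint(set(letters["NE"]))
        assert seps >= 9

    def test_single_level_rejected(self):
        frame = pd.DataFrame({"Subunit": ["SW"] * 10, "si": np.arange(10.0)})
        fit = smf.ols("si ~ 1", data=frame).fit()
        with pytest.raises(ValueError):
            tukey_hsd(fit, "Subunit")


class TestResidualize:
    def test_residuals_orthogonal_to_confounds(self):
        rng = np.random.default_rng(15)
        design = make_design(120, rng)
        X = rng.normal(size=(120, 6))
        X[:, 0] += 0.2 * design["length_cm"].to_numpy()
        resid = residualize(X, design)
        length = design["length_cm"].to_numpy()
        sex = (design["sex"] == "M").to_numpy(float)
        side = (design["side"] == "R").to_numpy(float)
        for conf in (length, sex, side):
            c = conf - conf.mean()
            corr = np.abs(resid.T @ c) / (
                np.linalg.norm(resid, axis=0) * np.linalg.norm(c)
            )
            assert corr.max() < 1e-10

    def test_matches_bruteforce_projection(self):
        rng = np.random.default_rng(16)
        design = make_design(60, rng)
        X = rng.normal(size=(60, 3))
        resid = residualize(X, design)
        Z = np.column_stack(
            [
                np.ones(60),
                design["length_cm"],
                (design["sex"] == "M").astype(float),
                (design["side"] == "R").astype(float),
            ]
        )
        P = Z @ np.linalg.pinv(Z)
        ref = X - P @ X
        ref -= ref.mean(axis=0)
        np.testing.assert_allclose(resid, ref, atol=1e-10)

    def test_subunit_never_a_confound(self):
        rng = np.random.default_rng(17)
        design = make_design(30, rng)
        with pytest.raises(ValueError):
            residualize(rng.normal(size=(30, 2)), design, terms=("Subunit", "Length"))

    def test_refit_confounds_on_residuals_gives_zero_coefficients(self):
        rng = np.random.default_rng(18)
        design = make_design(90, rng)
        X = rng.normal(size=(90, 4)) + 0.5 * design["length_cm"].to_numpy()[:, None]
        resid = residualize(X, design)
        again = residualize(resid, design)
        np.testing.assert_allclose(again, resid, atol=1e-10)
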