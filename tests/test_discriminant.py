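"""Discriminant analysis against brute-force and closed-form oracles."""

import numpy as np
import pandas as pd
import pytest
import scipy.linalg as sla
from scipy import stats as st

from herdvoice import (SynthConfig, binomial_chance_test,
                       chance_expectation, classify, fit_dfa,
                       generate_feature_table, loo_crossvalidate,
                       run_cross_valence_dfa, stepwise_select, wilks_lambda)
from herdvoice.discriminant import DFAError, _design, scatter_matrices
from tests.conftest import null_table


def toy_table(rng, n_groups=3, per_group=5, n_vars=2, sep=1.0):
    ids = np.repeat([f"g{k}" for k in range(n_groups)], per_group)
    X = rng.standard_normal((len(ids), n_vars))
    X[:, 0] += sep * np.repeat(np.arange(n_groups), per_group)
    df = pd.DataFrame(X, columns=[f"v{j}" for j in range(n_vars)])
    df["individual_id"] = ids
    return df


class TestWilksLambda:
    def test_identical_group_means_give_unity(self):
        df = pd.DataFrame({"v0": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
                           "individual_id": list("aaabbb")})
        assert wilks_lambda(df, ["v0"]) == pytest.approx(1.0)

    def test_zero_within_variance_gives_zero(self):
        df = pd.DataFrame({"v0": [0.0, 0.0, 0.0, 1.0, 1.0, 1.0],
                           "individual_id": list("aaabbb")})
        assert wilks_lambda(df, ["v0"]) == 0.0

    def test_matches_brute_force_cross_products(self, rng):
        df = toy_table(rng)
        lam = wilks_lambda(df, ["v0", "v1"])
        # independent brute force: explicit det(W)/det(T)
        X = df[["v0", "v1"]].to_numpy()
        y = df["individual_id"].to_numpy()
        T = np.cov(X.T, bias=False) * (len(X) - 1)
        W = sum(np.cov(X[y == k].T, bias=False) * ((y == k).sum() - 1)
                for k in np.unique(y))
        assert lam == pytest.approx(np.linalg.det(W) / np.linalg.det(T),
                                    abs=1e-10)

    def test_matches_statsmodels_manova(self, rng):
        from statsmodels.multivariate.manova import MANOVA
        df = toy_table(rng, n_groups=4, per_group=8, n_vars=3)
        lam = wilks_lambda(df, ["v0", "v1", "v2"])
        mv = MANOVA.from_formula("v0 + v1 + v2 ~ C(individual_id)", data=df)
        ref = mv.mv_test().results["C(individual_id)"]["stat"] \
            .loc["Wilks' lambda", "Value"]
        assert lam == pytest.approx(float(ref), abs=1e-10)

    def test_monotone_nonincreasing_in_added_variables(self, rng):
        df = toy_table(rng, n_groups=4, per_group=10, n_vars=5)
        cols = [f"v{j}" for j in range(5)]
        lams = [wilks_lambda(df, cols[:k]) for k in range(1, 6)]
        assert np.all(np.diff(lams) <= 1e-12)

    def test_collinear_variables_rejected(self, rng):
        df = toy_table(rng)
        df["dup"] = df["v0"]
        with pytest.raises(DFAError):
            wilks_lambda(df, ["v0", "dup"])


class TestStepwise:
    def test_selects_the_single_informative_variable(self, rng):
        df = toy_table(rng, n_groups=4, per_group=10, n_vars=6, sep=3.0)
        res = stepwise_select(df, [f"v{j}" for j in range(6)])
        # exhaustive single-variable search agrees on the winner
        best = min((wilks_lambda(df, [f"v{j}"]), f"v{j}") for j in range(6))
        assert res.selected[0] == best[1] == "v0"
        assert "v0" in res.selected

    def test_infinite_entry_threshold_selects_nothing(self, rng):
        df = toy_table(rng)
        res = stepwise_select(df, ["v0", "v1"], f_enter=np.inf)
        assert res.steps == [] and res.selected == []

    def test_duplicated_column_enters_once(self, rng):
        df = toy_table(rng, n_groups=4, per_group=10, sep=3.0)
        df["v0_copy"] = df["v0"]
        res = stepwise_select(df, ["v0", "v0_copy", "v1"])
        assert sum(v in res.selected for v in ("v0", "v0_copy")) == 1

    def test_lambda_nonincreasing_along_entry_steps(self, study_table):
        res = stepwise_select(study_table[study_table.valence == "positive"])
        lams = [lam for _, act, _, _, lam in res.steps if act == "enter"]
        assert np.all(np.diff(lams) <= 1e-12)


class TestFitDFA:
    def test_number_of_canonical_functions(self, study_table):
        pos = study_table[study_table.valence == "positive"]
        from herdvoice.params import PARAM_NAMES
        m10 = fit_dfa(pos, list(PARAM_NAMES[:10]))
        assert m10.coeffs_raw.shape[1] == 10
        m21 = fit_dfa(pos, list(PARAM_NAMES))
        assert m21.coeffs_raw.shape[1] == 12  # min(21, 13 - 1)

    def test_eigenvalues_match_generalized_eigenproblem(self, rng):
        df = toy_table(rng, n_groups=3, per_group=8, n_vars=4)
        cols = [f"v{j}" for j in range(4)]
        model = fit_dfa(df, cols)
        X, y, _ = _design(df, cols)
        W, T, _, _ = scatter_matrices(X, y)
        ref = np.sort(np.real(sla.eig(T - W, W)[0]))[::-1][:2]
        assert np.allclose(model.eigenvalues, ref, atol=1e-8)

    def test_standardized_coefficients_scaling(self, rng):
        df = toy_table(rng, n_groups=3, per_group=8, n_vars=3)
        model = fit_dfa(df, ["v0", "v1", "v2"])
        sd = np.sqrt(np.diag(model.pooled_cov))
        assert np.allclose(model.coeffs_std, model.coeffs_raw * sd[:, None])

    def test_equal_prior_midpoint_boundary_one_dimension(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 200)
        b = rng.normal(10, 1, 200)
        df = pd.DataFrame({"v0": np.r_[a, b],
                           "individual_id": ["a"] * 200 + ["b"] * 200})
        model = fit_dfa(df, ["v0"], priors="equal")
        lo = df.copy()
        test = pd.DataFrame({"v0": [4.9, 5.1],
                             "individual_id": ["a", "b"]})
        rep = classify(model, test)
        # both sides of the empirical midpoint classified to the near group
        mid = (a.mean() + b.mean()) / 2
        assert rep.confusion[0, 0] == (4.9 < mid)
        assert rep.confusion[1, 1] == (5.1 > mid)

    def test_unequal_priors_shift_boundary_by_closed_form(self):
        # 1-D LDA with priors (0.9, 0.1): boundary moves from the midpoint
        # by sigma^2 * ln(9) / delta-mu toward the minority group
        rng = np.random.default_rng(4)
        n1, n2 = 900, 100
        a = rng.normal(0, 1, n1)
        b = rng.normal(6, 1, n2)
        df = pd.DataFrame({"v0": np.r_[a, b],
                           "individual_id": ["a"] * n1 + ["b"] * n2})
        model = fit_dfa(df, ["v0"])   # proportional priors = 0.9 / 0.1
        mu1, mu2 = a.mean(), b.mean()
        s2 = float(model.pooled_cov[0, 0])
        boundary = (mu1 + mu2) / 2 + s2 * np.log(n1 / n2) / (mu2 - mu1)
        eps = 0.02
        test = pd.DataFrame({"v0": [boundary - eps, boundary + eps],
                             "individual_id": ["a", "b"]})
        rep = classify(model, test)
        assert rep.n_correct == 2


class TestClassification:
    def test_transfer_on_training_data_equals_resubstitution(self, rng):
        df = toy_table(rng, n_groups=3, per_group=10, sep=2.0)
        model = fit_dfa(df, ["v0", "v1"])
        a = classify(model, df, mode="resubstitution")
        b = classify(model, df, mode="transfer")
        assert np.array_equal(a.confusion, b.confusion)

    def test_separable_data_classified_perfectly(self):
        df = pd.DataFrame({
            "v0": [0.0, 0.01, 10.0, 10.01, 20.0, 20.01],
            "v1": [1.0, 1.01, 2.0, 1.99, 0.0, 0.01],
            "individual_id": list("aabbcc")})
        model = fit_dfa(df, ["v0", "v1"])
        assert classify(model, df).percent_correct == 100.0
        assert loo_crossvalidate(df, ["v0", "v1"]).percent_correct == 100.0

    def test_confusion_rows_sum_to_group_sizes(self, study_table):
        pos = study_table[study_table.valence == "positive"]
        res = stepwise_select(pos)
        model = fit_dfa(pos, res.selected)
        rep = classify(model, pos)
        sizes = pos.groupby("individual_id").size()
        assert np.array_equal(rep.confusion.sum(axis=1),
                              sizes[model.groups].to_numpy())

    def test_loo_needs_two_rows_per_group(self):
        df = pd.DataFrame({"v0": [0.0, 1.0, 2.0, 2.1],
                           "individual_id": ["a", "b", "c", "c"]})
        with pytest.raises(DFAError):
            loo_crossvalidate(df, ["v0"])

    def test_loo_not_better_than_resubstitution_usually(self):
        worse_or_equal = 0
        for seed in range(20):
            t = generate_feature_table(SynthConfig(seed=seed))
            pos = t[t.valence == "positive"]
            sel = stepwise_select(pos).selected
            model = fit_dfa(pos, sel)
            resub = classify(model, pos).percent_correct
            loo = loo_crossvalidate(pos, sel).percent_correct
            worse_or_equal += loo <= resub
        assert worse_or_equal >= 19


class TestChanceAndBinomial:
    @pytest.mark.parametrize("g,expected", [(13, 7.69), (2, 50.0),
                                            (100, 1.0)])
    def test_chance_expectation(self, g, expected):
        assert round(chance_expectation(g), 2) == expected

    def test_chance_needs_two_groups(self):
        with pytest.raises(ValueError):
            chance_expectation(1)

    def test_symmetric_case_is_exactly_one(self):
        assert binomial_chance_test(5, 10, 0.5).p_value == pytest.approx(1.0)

    def test_perfect_classification_is_extreme(self):
        assert binomial_chance_test(20, 20, 1 / 13).p_value < 1e-20

    def test_mode_outcome_is_one_under_minlike(self):
        n, p0 = 30, 1 / 13
        mode = int(np.floor((n + 1) * p0))
        assert binomial_chance_test(mode, n, p0).p_value == pytest.approx(
            1.0, abs=1e-12)

    @pytest.mark.parametrize("k,n,p0", [(7, 30, 1 / 13), (2, 30, 1 / 13),
                                        (12, 40, 0.25)])
    def test_minlike_matches_explicit_enumeration(self, k, n, p0):
        pmf = st.binom.pmf(np.arange(n + 1), n, p0)
        expected = pmf[pmf <= pmf[k] * (1 + 1e-7)].sum()
        assert binomial_chance_test(k, n, p0).p_value == pytest.approx(
            expected, rel=1e-9)

    def test_doubling_method(self):
        r = binomial_chance_test(9, 10, 0.5, method="doubling")
        assert r.p_value == pytest.approx(2 * st.binom.sf(8, 10, 0.5),
                                          rel=1e-12)


class TestCrossValence:
    def test_study_scale_run_beats_chance_everywhere(self, study_table):
        res = run_cross_valence_dfa(study_table, "positive")
        for name in ("resubstitution", "loo", "transfer"):
            assert res.reports[name].percent_correct > 7.69
            assert res.binomials[name].p_value < 0.001
        assert res.chance_percent == pytest.approx(100 / 13)
        assert len(res.scores) == len(study_table)

    def test_transfer_roughly_symmetric_between_valences(self):
        diffs = []
        for seed in range(10):
            t = generate_feature_table(SynthConfig(seed=seed))
            a = run_cross_valence_dfa(t, "positive")
            b = run_cross_valence_dfa(t, "negative")
            diffs.append(a.reports["transfer"].percent_correct
                         - b.reports["transfer"].percent_correct)
        assert abs(np.median(diffs)) < 10.0

    def test_null_herd_loo_near_chance(self):
        accs = [loo_crossvalidate(null_table(seed), [f"v{j}" for j in
                                                     range(5)]).percent_correct
                for seed in range(30)]
        assert abs(np.mean(accs) - 100 / 13) < 3.0

    def test_missing_valence_rejected(self, study_table):
        pos_only = study_table[study_table.valence == "positive"]
        with pytest.raises(DFAError):
            run_cross_valence_dfa(pos_only, "positive")
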