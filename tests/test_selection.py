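"""Cohort split, ICC / t-test / LASSO / stepwise stages, rad-score fits."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dceradiomics.features import FeatureTable
from dceradiomics.selection import (
    EmptyCandidateError,
    build_multiregional,
    fit_radscore,
    icc_2_1,
    icc_filter,
    lasso_select,
    run_endpoint,
    split_cohort,
    stepwise_select,
    ttest_filter,
)
from dceradiomics.synthetic import FeatureCohortConfig, simulate_feature_cohort


class TestSplitCohort:
    def test_four_to_one(self):
        train, val = split_cohort(np.arange(10), 0.8)
        assert len(train) == 8 and len(val) == 2
        assert set(train) == set(range(8))

    def test_five_patients(self):
        train, val = split_cohort(np.arange(5), 0.8)
        assert len(train) == 4 and len(val) == 1

    def test_reordered_input_same_patients(self):
        acq = np.array([3, 0, 4, 1, 2])
        train, val = split_cohort(acq, 0.8)
        # the latest acquisition (index 2 in input order) validates
        assert list(val) == [2]
        assert sorted(acq[train]) == [0, 1, 2, 3]

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError):
            split_cohort(np.arange(3), 0.1)


def anova_icc_2_1(x1, x2):
    """Oracle: two-way ANOVA mean squares written out longhand."""
    data = np.stack([x1, x2])  # raters x subjects
    k, n = data.shape
    grand = data.mean()
    msr = k * ((data.mean(axis=0) - grand) ** 2).sum() / (n - 1)
    msc = n * ((data.mean(axis=1) - grand) ** 2).sum() / (k - 1)
    sse = ((data - grand) ** 2).sum() - (n - 1) * msr - (k - 1) * msc
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestIccFilter:
    def test_identical_readers_icc_one(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(10, 5)),
                          columns=[f"intra_f{i}" for i in range(5)])
        retained, icc, undefined = icc_filter(df, df.copy())
        assert retained == list(df.columns)
        assert np.allclose(icc, 1.0)
        assert undefined == []

    def test_independent_noise_mostly_dropped(self):
        rng = np.random.default_rng(1)
        cols = [f"intra_f{i}" for i in range(1000)]
        a = pd.DataFrame(rng.normal(size=(30, 1000)), columns=cols)
        b = pd.DataFrame(rng.normal(size=(30, 1000)), columns=cols)
        retained, icc, _ = icc_filter(a, b)
        assert abs(icc.mean()) < 0.1
        assert len(retained) < 50

    def test_toy_table_matches_anova_oracle(self):
        x1 = np.array([9.0, 10.0, 12.0, 6.0, 8.0, 11.0])
        x2 = np.array([10.0, 11.0, 13.0, 7.0, 7.5, 12.0])
        ours = icc_2_1(x1[:, None], x2[:, None])[0]
        assert ours == pytest.approx(anova_icc_2_1(x1, x2))

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        x1 = rng.normal(size=12)
        x2 = x1 + rng.normal(0, 0.4, size=12)
        long = pd.DataFrame({
            "subject": np.tile(np.arange(12), 2),
            "rater": np.repeat(["a", "b"], 12),
            "score": np.concatenate([x1, x2]),
        })
        ref = pg.intraclass_corr(long, targets="subject", raters="rater",
                                 ratings="score")
        # single-rater absolute agreement: labelled ICC2 or ICC(A,1)
        ref_icc2 = ref.loc[ref["Type"].isin(["ICC2", "ICC(A,1)"]), "ICC"].iloc[0]
        assert icc_2_1(x1[:, None], x2[:, None])[0] == pytest.approx(ref_icc2)

    def test_zero_variance_feature_flagged(self):
        df1 = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        df2 = df1.copy()
        retained, icc, undefined = icc_filter(df1, df2)
        assert undefined == ["a"]
        assert retained == ["b"]


class TestTtestFilter:
    def test_identical_distribution_dropped(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 1.0, 2.0]})
        retained, p = ttest_filter(df, [0, 0, 1, 1])
        assert p["a"] == pytest.approx(1.0)
        assert retained == []

    def test_label_like_feature_retained(self):
        rng = np.random.default_rng(0)
        y = np.repeat([0, 1], 10)
        df = pd.DataFrame({"a": y + rng.normal(0, 0.01, 20)})
        retained, p = ttest_filter(df, y)
        assert retained == ["a"]
        assert p["a"] < 1e-6

    def test_welch_example(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0, 3.0, 4.0, 5.0, 6.0]})
        y = [1, 1, 1, 1, 0, 0, 0, 0]
        retained, p = ttest_filter(df, y, alpha=0.1)
        ref = stats.ttest_ind([1, 2, 3, 4], [3, 4, 5, 6], equal_var=False)
        assert ref.statistic == pytest.approx(-2.1909, abs=1e-4)
        assert p["a"] == pytest.approx(ref.pvalue)
        assert p["a"] < 0.1 and retained == ["a"]


def _informative_frame(n=200, p_noise=50, effect=2.0, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.permutation(np.repeat([0, 1], n // 2))
    X = rng.standard_normal((n, p_noise + 1))
    X[:, 0] += effect * y
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    cols = ["signal"] + [f"noise{i}" for i in range(p_noise)]
    return pd.DataFrame(X, columns=cols), y


class TestLassoSelect:
    def test_lambda_max_selects_nothing(self):
        df, y = _informative_frame(seed=1)
        from dceradiomics.selection import _lambda_max
        lam_max = _lambda_max(df.to_numpy(), y)
        survivors, _ = lasso_select(df, y, lambda_override=lam_max * 1.001)
        assert survivors == []

    def test_informative_feature_recovered_across_seeds(self):
        hits = 0
        for seed in range(20):
            df, y = _informative_frame(seed=seed)
            survivors, lam = lasso_select(df, y, seed=seed)
            hits += "signal" in survivors
            assert lam > 0
        assert hits >= 19  # >= 95% of seeds

    def test_null_selects_few(self):
        counts = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            y = rng.permutation(np.repeat([0, 1], 100))
            X = rng.standard_normal((200, 100))
            df = pd.DataFrame(X, columns=[f"n{i}" for i in range(100)])
            survivors, _ = lasso_select(df, y, seed=seed)
            counts.append(len(survivors))
        assert np.median(counts) <= 5

    def test_constant_labels_rejected(self):
        df, _ = _informative_frame()
        with pytest.raises(ValueError):
            lasso_select(df, np.ones(len(df), dtype=int))

    def test_one_se_rule_is_sparser_or_equal(self):
        df, y = _informative_frame(seed=3)
        s_min, lam_min = lasso_select(df, y, seed=3, lambda_rule="min")
        s_1se, lam_1se = lasso_select(df, y, seed=3, lambda_rule="1se")
        assert lam_1se >= lam_min
        assert len(s_1se) <= len(s_min)


class TestStepwise:
    def test_single_informative_feature_kept(self):
        df, y = _informative_frame(p_noise=3, seed=4)
        survivors, aic, ok = stepwise_select(df, y, ["signal"])
        assert survivors == ["signal"]
        assert ok

    def test_duplicate_feature_removed(self):
        df, y = _informative_frame(p_noise=1, seed=5)
        df["dup"] = df["signal"] + np.random.default_rng(5).normal(0, 1e-6, len(df))
        survivors, _, _ = stepwise_select(df, y, ["signal", "dup"])
        assert len(survivors) == 1

    def test_fixed_point_when_all_features_matter(self):
        rng = np.random.default_rng(6)
        n = 300
        x1, x2 = rng.standard_normal(n), rng.standard_normal(n)
        logit = 2.0 * x1 - 2.0 * x2
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        df = pd.DataFrame({"x1": x1, "x2": x2})
        survivors, _, _ = stepwise_select(df, y, ["x1", "x2"])
        assert survivors == ["x1", "x2"]

    def test_pure_noise_pruned(self):
        rng = np.random.default_rng(7)
        y = rng.permutation(np.repeat([0, 1], 100))
        df = pd.DataFrame(rng.standard_normal((200, 5)),
                          columns=[f"n{i}" for i in range(5)])
        survivors, aic, _ = stepwise_select(df, y, list(df.columns))
        assert len(survivors) < 5


def irls_logistic(X, y, iters=200):
    """Oracle: hand-rolled iteratively reweighted least squares."""
    X = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(X.shape[1])
    for _ in range(iters):
        eta = X @ beta
        p = 1 / (1 + np.exp(-eta))
        W = p * (1 - p)
        z = eta + (y - p) / np.clip(W, 1e-12, None)
        beta_new = np.linalg.solve((X * W[:, None]).T @ X, (X * W[:, None]).T @ z)
        if np.max(np.abs(beta_new - beta)) < 1e-12:
            beta = beta_new
            break
        beta = beta_new
    return beta


class TestFitRadscore:
    def test_separable_feature_training_auc_one(self):
        from dceradiomics.evaluation import roc_auc
        rng = np.random.default_rng(8)
        y = np.repeat([0, 1], 15)
        df = pd.DataFrame({"a": y + rng.normal(0, 0.05, 30)})
        model = fit_radscore(df, y, ["a"], "intra", "er")
        scores = model.rad_score(df)
        assert roc_auc(scores, y).auc == 1.0

    def test_intercept_only_constant_score(self):
        df = pd.DataFrame({"a": [0.0, 1.0, 2.0, 3.0]})
        model = fit_radscore(df, [0, 1, 0, 1], [], "multi")
        assert model.coefficients == {}
        assert model.rad_score(df).nunique() == 1

    def test_matches_hand_irls(self):
        rng = np.random.default_rng(9)
        n = 60
        x = rng.standard_normal((n, 2))
        logit = 0.5 + 1.0 * x[:, 0] - 0.7 * x[:, 1]
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        df = pd.DataFrame(x, columns=["a", "b"])
        model = fit_radscore(df, y, ["a", "b"], "intra")
        beta = irls_logistic(x, y)
        assert model.intercept == pytest.approx(beta[0], abs=1e-5)
        assert model.coefficients["a"] == pytest.approx(beta[1], abs=1e-5)
        assert model.coefficients["b"] == pytest.approx(beta[2], abs=1e-5)

    def test_json_round_trip(self):
        from dceradiomics.selection import RadScoreModel
        model = RadScoreModel("er", "multi", 0.25, {"a": -1.5, "b": 2.0})
        again = RadScoreModel.from_json(model.to_json())
        assert again == model


class TestMultiregional:
    def test_duplicates_removed_before_lasso(self):
        df, y = _informative_frame(p_noise=5, seed=10)
        model, sel = build_multiregional(
            ["signal", "noise0"], ["signal", "noise1"], df, y, seed=0
        )
        assert sel.stage_survivors["candidates"].count("signal") == 1

    def test_empty_peri_degenerates_to_intra(self):
        df, y = _informative_frame(p_noise=3, seed=11)
        model, sel = build_multiregional(["signal"], [], df, y, seed=0)
        assert set(sel.stage_survivors["stepwise"]) <= {"signal"}
        assert model.region_scope == "multi"

    def test_empty_union_rejected(self):
        df, y = _informative_frame(seed=12)
        with pytest.raises(EmptyCandidateError):
            build_multiregional([], [], df, y, seed=0)


def _cohort_tables(seed=0, **cfg_kwargs):
    cfg = FeatureCohortConfig(**{"n_patients": 150, "n_intra": 30,
                                 "n_peri": 30, **cfg_kwargs})
    r1, r2, labels = simulate_feature_cohort(cfg, seed=seed)
    train, val = split_cohort(labels["acquisition_index"].to_numpy())
    return FeatureTable(r1), FeatureTable(r2), labels, train, val


class TestRunEndpoint:
    def test_survivor_nesting(self):
        t1, t2, labels, train, val = _cohort_tables(seed=1)
        res = run_endpoint(t1, t2, labels["er_label"].to_numpy(), train, val,
                           "er", seed=1)
        for region in ("intra", "peri"):
            sel = res.selection[region]
            sel.assert_nested()
            assert all(sel.icc_values[f] > 0.8
                       for f in sel.stage_survivors["ttest"])
            assert all(sel.p_values[f] < 0.1
                       for f in sel.stage_survivors["lasso"])

    def test_er_and_pr_select_independently(self):
        t1, t2, labels, train, val = _cohort_tables(seed=2)
        res_er = run_endpoint(t1, t2, labels["er_label"].to_numpy(), train, val,
                              "er", seed=2)
        res_pr = run_endpoint(t1, t2, labels["pr_label"].to_numpy(), train, val,
                              "pr", seed=2)
        er_set = set(res_er.selection["intra"].stage_survivors["stepwise"])
        pr_set = set(res_pr.selection["intra"].stage_survivors["stepwise"])
        assert er_set != pr_set  # planted effects differ by endpoint

    def test_no_ttest_survivor_raises_explicitly(self):
        rng = np.random.default_rng(3)
        cols = [f"intra_f{i}" for i in range(4)] + [f"peri_f{i}" for i in range(4)]
        df = pd.DataFrame(np.tile(rng.standard_normal((1, 8)), (40, 1))
                          + rng.normal(0, 1e-9, (40, 8)), columns=cols)
        # make features reproducible across readers but uninformative:
        t1, t2 = FeatureTable(df), FeatureTable(df.copy())
        y = np.tile([0, 1], 20)
        with pytest.raises(EmptyCandidateError, match="empty candidate set"):
            run_endpoint(t1, t2, y, np.arange(32), np.arange(32, 40), "er",
                         seed=3, alpha=1e-12)

    def test_validation_rows_never_influence_fit(self):
        t1, t2, labels, train, val = _cohort_tables(seed=4)
        y = labels["er_label"].to_numpy()
        res_a = run_endpoint(t1, t2, y, train, val, "er", seed=4)

        # scramble every validation row (features and labels)
        rng = np.random.default_rng(99)
        df1, df2 = t1.df.copy(), t2.df.copy()
        df1.iloc[val] = rng.normal(50, 100, (len(val), df1.shape[1]))
        df2.iloc[val] = rng.normal(50, 100, (len(val), df2.shape[1]))
        y_b = y.copy()
        y_b[val] = rng.integers(0, 2, len(val))
        res_b = run_endpoint(FeatureTable(df1), FeatureTable(df2), y_b,
                             train, val, "er", seed=4)

        for scope in ("intra", "peri", "multi"):
            assert res_a.models[scope] == res_b.models[scope]
        assert res_a.table.means.equals(res_b.table.means)
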