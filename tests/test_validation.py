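"""Rank concordance, ROC, outcome regressions, group tests, DD comparison."""

import dataclasses
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aweni import (
    compute_scores,
    dd_comparison,
    default_config,
    generate_survey,
    get_fixture,
    group_tests,
    kendall_tau,
    outcome_regression,
    roc_auc,
    run_abbreviation,
)
from aweni.lasso import LassoConfig
from tests.conftest import scaled_config


def brute_force_kendall(x, y):
    """Exhaustive pair enumeration: S, tau-a, tau-b."""
    n = len(x)
    S = sum(
        np.sign(x[i] - x[j]) * np.sign(y[i] - y[j])
        for i, j in itertools.combinations(range(n), 2)
    )
    n0 = n * (n - 1) / 2
    tie = lambda v: sum(
        c * (c - 1) / 2 for c in pd.Series(v).value_counts() if c > 1
    )
    return S, S / n0, S / np.sqrt((n0 - tie(x)) * (n0 - tie(y)))


class TestKendallTau:
    def test_identity_gives_one(self):
        x = np.array([0.3, 0.1, 0.9, 0.5])
        assert kendall_tau(x, x).tau_b == pytest.approx(1.0)

    def test_reversal_gives_minus_one(self):
        assert kendall_tau([1, 2, 3, 4], [4, 3, 2, 1]).tau_b == pytest.approx(-1.0)

    def test_tied_example_matches_pair_enumeration(self):
        x, y = [1, 2, 2, 3], [1, 3, 2, 4]
        res = kendall_tau(x, y)
        S, tau_a, tau_b = brute_force_kendall(x, y)
        assert res.score == pytest.approx(S)
        assert res.tau_a == pytest.approx(tau_a)
        assert res.tau_b == pytest.approx(tau_b)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_scipy_on_random_tied_data(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 5, 60).astype(float)
        y = x + rng.integers(0, 4, 60)
        res = kendall_tau(x, y)
        ref = stats.kendalltau(x, y)
        assert res.tau_b == pytest.approx(ref.statistic, abs=1e-12)

    def test_monotone_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=40)
        assert kendall_tau(x, 2.5 * x + 7.0).tau_b == pytest.approx(1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            kendall_tau([1.0, 1.0, 1.0], [1, 2, 3])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            kendall_tau([1, 2], [1, 2, 3])


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert res.auc == 1.0
        assert res.upper <= 1.0

    def test_constant_score_is_chance(self):
        assert roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]).auc == pytest.approx(0.5)

    def test_three_of_four_pairs_concordant(self):
        res = roc_auc([0.2, 0.4, 0.6, 0.8], [0, 1, 0, 1])
        assert res.auc == pytest.approx(0.75)
        assert res.n_positive == 2 and res.n_negative == 2

    def test_hanley_mcneil_se_hand_computation(self):
        res = roc_auc([0.2, 0.4, 0.6, 0.8], [0, 1, 0, 1])
        a = 0.75
        q1, q2 = a / (2 - a), 2 * a**2 / (1 + a)
        var = (a * (1 - a) + (2 - 1) * (q1 - a**2) + (2 - 1) * (q2 - a**2)) / 4
        assert res.se == pytest.approx(np.sqrt(var))
        assert res.lower == pytest.approx(max(0.0, a - 1.96 * res.se))

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_sklearn_on_random_data(self, seed):
        metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(seed)
        score = rng.normal(size=80)
        truth = (score + rng.normal(0, 1, 80) > 0).astype(int)
        assert roc_auc(score, truth).auc == pytest.approx(
            metrics.roc_auc_score(truth, score), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([0.1, 0.2], [1, 1])

    def test_own_thresholded_status_gives_auc_one(self, survey, full_schema):
        sc = compute_scores(survey, full_schema)
        res = roc_auc(sc["composite"], sc["status"])
        assert res.auc == 1.0


def outcome_frame(bmi, pregnant=None, food_groups=None, group="index_woman"):
    n = len(bmi)
    return pd.DataFrame(
        {
            "bmi": bmi,
            "pregnant": pregnant if pregnant is not None else [False] * n,
            "food_groups": food_groups if food_groups is not None else [5] * n,
            "group": [group] * n,
            "age": np.linspace(20, 40, n),
            "site": ["s1"] * n,
        }
    )


class TestOutcomeRegression:
    def test_probit_intercept_zero_at_balanced_outcome(self):
        # y independent of status with conditional means exactly 0.5
        n = 200
        df = outcome_frame(
            bmi=[20.0] * n, food_groups=[4, 6] * (n // 2)
        )
        status = np.tile([0, 0, 1, 1], n // 4)
        res = outcome_regression(df, status, "mdd", controls=[])
        assert res.model == "probit"
        assert res.params["const"] == pytest.approx(0.0, abs=1e-5)
        assert res.params["empowered"] == pytest.approx(0.0, abs=1e-5)

    def test_overweight_respondent_excluded_from_bmi_models(self):
        df = outcome_frame(bmi=[19.0, 21.0, 24.0, 27.0, 20.0, 22.0])
        status = [0, 1, 0, 1, 0, 1]
        res = outcome_regression(df, status, "bmi", controls=["age"])
        assert res.n == 5  # the BMI-27 row is dropped
        assert "BMI < 25" in res.restriction

    def test_pregnant_excluded_from_bmi_but_controlled_in_mdd(self):
        df = outcome_frame(
            bmi=[19.0, 21.0, 20.0, 22.0, 21.0, 19.5],
            pregnant=[True, False, False, False, False, False],
            food_groups=[3, 6, 4, 7, 5, 2],
        )
        status = [0, 1, 0, 1, 0, 1]
        res_bmi = outcome_regression(df, status, "bmi", controls=["age"])
        assert res_bmi.n == 5
        res_mdd = outcome_regression(df, status, "mdd", controls=["age"])
        assert res_mdd.n == 6
        assert "pregnant" in res_mdd.params.index

    def test_log_bmi_is_ols_with_robust_errors(self):
        rng = np.random.default_rng(4)
        df = outcome_frame(bmi=rng.uniform(17, 24, 50))
        status = rng.integers(0, 2, 50)
        res = outcome_regression(df, status, "log-bmi", controls=["age"])
        assert res.model == "ols"
        assert "r_squared" in res.fit_stat

    def test_bmi_effect_recovered_within_robust_interval(self):
        # generator truth: empowerment raises BMI by 0.8 at n=4000
        cfg = scaled_config(seed=0, factor=4000 / 2398)
        df = generate_survey(cfg)
        sc = compute_scores(df, get_fixture("weni33"))
        res = outcome_regression(
            df, sc["status"], "bmi", controls=["site", "group", "age"]
        )
        lo, hi = res.conf_int.loc["empowered"]
        assert lo <= cfg.bmi_effect <= hi

    def test_reference_levels_reported(self, small_survey, full_schema):
        sc = compute_scores(small_survey, full_schema)
        res = outcome_regression(
            small_survey, sc["status"], "bmi", controls=["site", "group", "age"]
        )
        assert res.reference_levels["site"] == "siteA"
        assert res.n == int(
            (
                small_survey["bmi"].notna()
                & (small_survey["bmi"] < 25)
                & ~small_survey["pregnant"]
            ).sum()
        )

    def test_unknown_outcome_rejected(self, small_survey):
        with pytest.raises(ValueError, match="outcome"):
            outcome_regression(small_survey, [0] * len(small_survey), "anemia")


class TestGroupTests:
    def test_null_case_identical_distributions(self):
        # two interleaved copies of one sample -> t = 0, p = 1
        vals = np.array([18.0, 19.0, 20.0, 21.0, 22.0] * 2)
        status = np.array([0] * 5 + [1] * 5)
        groups = np.array(["g"] * 10)
        table = group_tests(vals, status, groups)
        assert table.loc["g", "t_stat"] == pytest.approx(0.0, abs=1e-12)
        assert table.loc["g", "p_mean"] == pytest.approx(1.0)

    def test_welch_statistic_matches_hand_formula(self):
        rng = np.random.default_rng(5)
        d = rng.normal(19.88, 2.0, 305)
        e = rng.normal(21.66, 2.2, 210)
        table = group_tests(
            np.concatenate([d, e]),
            np.array([0] * 305 + [1] * 210),
            np.array(["all_women"] * 515),
        )
        se = np.sqrt(d.var(ddof=1) / 305 + e.var(ddof=1) / 210)
        t_hand = (e.mean() - d.mean()) / se
        assert table.loc["all_women", "t_stat"] == pytest.approx(t_hand, rel=1e-10)

    def test_proportion_z_matches_pooled_formula(self):
        # 174/305 disempowered vs 164/210 empowered with normal BMI
        binary = np.array([1.0] * 174 + [0.0] * 131 + [1.0] * 164 + [0.0] * 46)
        status = np.array([0] * 305 + [1] * 210)
        groups = np.array(["g"] * 515)
        outcome = binary.copy()  # placeholder continuous outcome
        table = group_tests(outcome, status, groups, binary=binary)
        p1, n1 = 164 / 210, 210
        p0, n0 = 174 / 305, 305
        pool = (164 + 174) / 515
        z_hand = (p1 - p0) / np.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n0))
        assert table.loc["g", "z_stat"] == pytest.approx(z_hand, rel=1e-10)

    def test_one_class_stratum_flagged(self):
        vals = np.array([19.0, 20.0, 21.0, 22.0])
        status = np.array([1, 1, 1, 1])
        groups = np.array(["g"] * 4)
        table = group_tests(vals, status, groups)
        assert np.isnan(table.loc["g", "p_mean"])
        assert table.loc["g", "flag"] == "one-class"


class TestDDComparison:
    def test_identity_schemas_identical_columns(self, survey, full_schema):
        sc = compute_scores(survey, full_schema)
        table = dd_comparison(sc, sc)
        np.testing.assert_allclose(table["full_pct"], table["abbreviated_pct"])

    def test_all_ones_saturates_every_dimension(self, full_schema, abbrev_schema):
        df = pd.DataFrame(
            [{n: 1.0 for n in full_schema.names}] * 3
        )
        sf = compute_scores(df, full_schema)
        sa = compute_scores(df, abbrev_schema)
        table = dd_comparison(sf, sa)
        assert (table == 100.0).all().all()

    def test_four_respondent_hand_counts(self, full_schema, abbrev_schema):
        rows = []
        for k in (0, 10, 22, 33):  # 0, some, most, all indicators on
            rows.append({n: float(i < k) for i, n in enumerate(full_schema.names)})
        df = pd.DataFrame(rows)
        sf = compute_scores(df, full_schema)
        sa = compute_scores(df, abbrev_schema)
        table = dd_comparison(sf, sa, threshold=0.5)
        for dim in table.index:
            col = "composite" if dim == "composite" else dim
            assert table.loc[dim, "full_pct"] == pytest.approx(
                100.0 * (sf[col] >= 0.5).mean()
            )
            assert table.loc[dim, "abbreviated_pct"] == pytest.approx(
                100.0 * (sa[col] >= 0.5).mean()
            )

    def test_mismatched_respondents_rejected(self, survey, full_schema):
        sc = compute_scores(survey, full_schema)
        with pytest.raises(ValueError, match="different respondents"):
            dd_comparison(sc, sc.iloc[:-1])


class TestPipelineProperties:
    def test_selection_beats_random_subsets(self, survey, full_schema):
        """The chosen subset tracks the full score better than chance."""
        rep = run_abbreviation(
            survey, full_schema, k=20, approaches=("cv", "bic"),
            train_sites=["siteA", "siteB"],
            config=LassoConfig(n_lambda=60, cv_folds=5),
        )
        sf = compute_scores(survey, full_schema)
        sel = compute_scores(survey, full_schema.subset(rep.chosen))
        tau_sel = kendall_tau(sf["composite"], sel["composite"]).tau_b
        rng = np.random.default_rng(99)
        wins = 0
        n_rep = 100
        for _ in range(n_rep):
            rand = rng.choice(full_schema.names, size=20, replace=False)
            sr = compute_scores(survey, full_schema.subset(rand))
            if tau_sel > kendall_tau(sf["composite"], sr["composite"]).tau_b:
                wins += 1
        assert wins / n_rep >= 0.95

    def test_robust_interval_coverage_of_generator_effects(self):
        """95% CIs for the BMI and MDD effects cover the (pseudo-)truth
        in about 95% of replicates."""
        # pseudo-true MDD probit coefficient: the generator ties food groups
        # to the latent factor, so the status coefficient is the induced
        # large-sample value, computed once at large n
        big = generate_survey(scaled_config(seed=777, factor=25))
        sc_big = compute_scores(big, get_fixture("weni33"))
        mdd_truth = outcome_regression(
            big, sc_big["status"], "mdd", controls=["site", "group", "age"]
        ).params["empowered"]

        schema = get_fixture("weni33")
        bmi_cover = mdd_cover = 0
        n_rep = 200
        for i in range(n_rep):
            cfg = scaled_config(seed=10_000 + i, factor=0.25)
            df = generate_survey(cfg)
            sc = compute_scores(df, schema)
            r_bmi = outcome_regression(
                df, sc["status"], "bmi", controls=["site", "group", "age"]
            )
            lo, hi = r_bmi.conf_int.loc["empowered"]
            bmi_cover += lo <= cfg.bmi_effect <= hi
            r_mdd = outcome_regression(
                df, sc["status"], "mdd", controls=["site", "group", "age"]
            )
            lo, hi = r_mdd.conf_int.loc["empowered"]
            mdd_cover += lo <= mdd_truth <= hi
        assert 0.91 <= bmi_cover / n_rep <= 0.99
        assert 0.91 <= mdd_cover / n_rep <= 0.99
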