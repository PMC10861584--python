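"""Statistical cascade: tests, ROC, cut-offs, 2x2 metrics, logistic fits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import mannwhitneyu, norm

import statsmodels.api as sm

from conftest import two_class_config
from urovoc.diagnostics import (
    ContingencyTable,
    SeparationError,
    auc_inference,
    chi_square_2x2,
    combined_biomarker,
    confusion_from_rates,
    diagnostic_metrics,
    empirical_auc,
    fit_logistic_univariable,
    screen_features,
    spearman_rho,
    two_sample_t,
    youden_cutoff,
)
from urovoc.features import build_feature_table
from urovoc.simulate import generate_cohort, default_config


class TestTwoSampleT:
    def test_identical_groups_p_one(self):
        assert two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])[1] == pytest.approx(1.0)

    def test_large_shift_tiny_p(self):
        a = np.array([1.0, 2.0, 3.0])
        assert two_sample_t(a, a + 100.0)[1] < 1e-6

    def test_hand_computed_pooled_t(self):
        # pooled variance 0.5, se = sqrt(0.5 * (1/2 + 1/2)), t = -2/0.7071
        stat, _ = two_sample_t([1.0, 2.0], [3.0, 4.0], variant="student")
        assert stat == pytest.approx(-2.828427, abs=1e-6)

    def test_zero_variance_limits(self):
        assert two_sample_t([5.0, 5.0], [5.0, 5.0])[1] == 1.0
        assert two_sample_t([5.0, 5.0], [7.0, 7.0])[1] == 0.0

    def test_welch_differs_under_unequal_variances(self):
        a = [1.0, 2.0, 3.0, 4.0]
        b = [10.0, 30.0, 50.0, 70.0, 90.0]
        assert two_sample_t(a, b, "student")[1] != two_sample_t(a, b, "welch")[1]


class TestChiSquare:
    def test_independent_table_stat_zero(self):
        stat, p = chi_square_2x2(ContingencyTable(10, 10, 10, 10))
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_direct_expected_count_enumeration(self):
        tab = ContingencyTable(13, 4, 19, 28)
        obs = np.array([[13, 19], [4, 28]], dtype=float)
        n = obs.sum()
        exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
        stat, _ = chi_square_2x2(tab)
        assert stat == pytest.approx(((obs - exp) ** 2 / exp).sum(), rel=1e-12)

    def test_doubling_cells_doubles_statistic(self):
        s1, _ = chi_square_2x2(ContingencyTable(13, 4, 19, 28))
        s2, _ = chi_square_2x2(ContingencyTable(26, 8, 38, 56))
        assert s2 == pytest.approx(2.0 * s1, rel=1e-12)

    def test_zero_margin_errors(self):
        with pytest.raises(ValueError):
            chi_square_2x2(ContingencyTable(0, 0, 10, 10))


class TestSpearman:
    def test_monotone_relations(self):
        x = np.arange(10.0)
        assert spearman_rho(x, x**3)[0] == pytest.approx(1.0)
        assert spearman_rho(x, -x)[0] == pytest.approx(-1.0)

    def test_constant_input_signalled(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_gap_slope_collinearity_on_near_constant_fall_time(self):
        """With almost no fall-time spread, gap and SL of the same cycle are
        nearly proportional: the two features carry the same information."""
        cfg = default_config(seed=21, fall_time_sd=0.3, noise_sd=0.0)
        traces, _ = generate_cohort(cfg)
        ft = build_feature_table(traces)
        rho, _ = spearman_rho(ft["gap1S2"], ft["SL1S2"])
        assert rho > 0.95


class TestAuc:
    def test_perfect_separation_and_ties(self):
        assert empirical_auc([1, 2, 8, 9], [0, 0, 1, 1]) == 1.0
        assert empirical_auc([5, 5, 5, 5], [0, 0, 1, 1]) == 0.5

    def test_brute_force_four_pairs(self):
        assert empirical_auc([3, 5, 1, 4], [1, 1, 0, 0]) == 0.75

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=50, deadline=None)
    def test_equals_mann_whitney_u(self, seed):
        rng = np.random.default_rng(seed)
        n1, n0 = rng.integers(3, 20, size=2)
        cases = rng.integers(0, 10, size=n1).astype(float)
        controls = rng.integers(0, 10, size=n0).astype(float)
        scores = np.concatenate([cases, controls])
        y = np.r_[np.ones(n1), np.zeros(n0)]
        u = mannwhitneyu(cases, controls, alternative="two-sided").statistic
        assert empirical_auc(scores, y) == pytest.approx(u / (n1 * n0), rel=1e-12)

    def test_one_class_absent_errors(self):
        with pytest.raises(ValueError):
            empirical_auc([1.0, 2.0], [1, 1])


class TestAucInference:
    def test_hanley_mcneil_se_matches_hand_formula(self):
        scores = np.array([3.0, 5.0, 1.0, 4.0])
        y = np.array([1, 1, 0, 0])
        res = auc_inference(scores, y)
        a = 0.75
        q1, q2 = a / (2 - a), 2 * a * a / (1 + a)
        var = (a * (1 - a) + (2 - 1) * (q1 - a * a) + (2 - 1) * (q2 - a * a)) / 4
        assert res.se == pytest.approx(math.sqrt(var), rel=1e-12)
        assert res.ci_high <= 1.0 and res.ci_low >= 0.0

    def test_symmetric_scores_p_one(self):
        res = auc_inference([1, 2, 1, 2], [1, 1, 0, 0])
        assert res.auc == 0.5
        assert res.p_value == pytest.approx(1.0)

    def test_delong_close_to_hanley_on_continuous_scores(self):
        rng = np.random.default_rng(0)
        scores = np.r_[rng.normal(1, 1, 40), rng.normal(0, 1, 40)]
        y = np.r_[np.ones(40), np.zeros(40)]
        hm = auc_inference(scores, y, "hanley_mcneil")
        dl = auc_inference(scores, y, "delong")
        assert dl.auc == hm.auc
        assert dl.se == pytest.approx(hm.se, rel=0.25)

    def test_ci_width_shrinks_with_sample_size(self):
        rng = np.random.default_rng(1)
        widths = []
        for n in (16, 32, 64, 128):
            scores = np.r_[rng.normal(1, 1, n), rng.normal(0, 1, n)]
            y = np.r_[np.ones(n), np.zeros(n)]
            r = auc_inference(scores, y)
            widths.append(r.se)
        assert all(a > b for a, b in zip(widths, widths[1:]))


class TestYouden:
    def test_tie_broken_by_accuracy_then_smaller_cutoff(self):
        cut, m = youden_cutoff([3, 5, 1, 4], [1, 1, 0, 0])
        assert cut == 3.0
        assert m.youden_j == pytest.approx(0.5)
        assert m.accuracy == pytest.approx(0.75)

    def test_perfectly_separated_returns_smallest_case_score(self):
        cut, m = youden_cutoff([10, 12, 1, 2], [1, 1, 0, 0])
        assert cut == 10.0
        assert m.youden_j == pytest.approx(1.0)

    def test_shift_equivariance(self):
        scores = np.array([3.0, 5.0, 1.0, 4.0, 2.0, 7.0])
        y = np.array([1, 1, 0, 0, 0, 1])
        c0, _ = youden_cutoff(scores, y)
        c1, _ = youden_cutoff(scores + 11.5, y)
        assert c1 == pytest.approx(c0 + 11.5)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=50, deadline=None)
    def test_returned_j_is_exhaustively_optimal(self, seed):
        rng = np.random.default_rng(seed)
        n1, n0 = rng.integers(2, 10, size=2)
        scores = rng.integers(0, 8, size=n1 + n0).astype(float)
        y = np.r_[np.ones(n1), np.zeros(n0)]
        _, m = youden_cutoff(scores, y)
        cases, controls = scores[y == 1], scores[y == 0]
        for c in np.unique(scores):
            sens = np.mean(cases >= c)
            spec = np.mean(controls < c)
            assert m.youden_j >= sens + spec - 1.0 - 1e-12


class TestContingency:
    @pytest.mark.parametrize(
        "sens,spec,tp,fp,fn,tn",
        [
            (0.406, 0.875, 13, 4, 19, 28),
            (0.750, 0.594, 24, 13, 8, 19),
            (1.0, 1.0, 32, 0, 0, 32),
        ],
    )
    def test_reconstruction_from_rates(self, sens, spec, tp, fp, fn, tn):
        tab = confusion_from_rates(sens, spec, 32, 32)
        assert (tab.tp, tab.fp, tab.fn, tab.tn) == (tp, fp, fn, tn)

    def test_perfect_table_metrics(self):
        m = diagnostic_metrics(ContingencyTable(10, 0, 0, 10))
        assert m.sensitivity == m.specificity == m.ppv == m.npv == m.accuracy == 1.0
        assert math.isinf(m.odds_ratio)

    @given(
        st.integers(1, 60), st.integers(1, 60), st.integers(1, 60), st.integers(1, 60)
    )
    @settings(max_examples=60, deadline=None)
    def test_metric_conservation_on_integer_tables(self, tp, fp, fn, tn):
        tab = ContingencyTable(tp, fp, fn, tn)
        m = diagnostic_metrics(tab)
        lhs = m.sensitivity * tab.n_pos + m.specificity * tab.n_neg
        assert lhs == pytest.approx(tp + tn, rel=1e-12)
        assert m.accuracy * tab.total == pytest.approx(tp + tn, rel=1e-12)
        assert m.or_ci_low <= m.odds_ratio <= m.or_ci_high


class TestLogistic:
    @given(
        st.integers(1, 40), st.integers(1, 40), st.integers(1, 40), st.integers(1, 40)
    )
    @settings(max_examples=30, deadline=None)
    def test_saturated_2x2_identity_with_woolf(self, tp, fp, fn, tn):
        """For a binary predictor the ML logistic OR equals the cross-product
        OR and the Wald CI equals the Woolf CI."""
        tab = ContingencyTable(tp, fp, fn, tn)
        m = diagnostic_metrics(tab)
        x = np.r_[np.ones(tp), np.zeros(fn), np.ones(fp), np.zeros(tn)]
        y = np.r_[np.ones(tp + fn), np.zeros(fp + tn)]
        orr, lo, hi, _ = fit_logistic_univariable(x, y)
        assert orr == pytest.approx(m.odds_ratio, rel=1e-6)
        assert lo == pytest.approx(m.or_ci_low, rel=1e-5)
        assert hi == pytest.approx(m.or_ci_high, rel=1e-5)

    def test_matches_statsmodels_on_continuous_predictor(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=80)
        y = (rng.uniform(size=80) < 1 / (1 + np.exp(-(0.5 + 1.2 * x)))).astype(float)
        orr, lo, hi, p = fit_logistic_univariable(x, y)
        fit = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert math.log(orr) == pytest.approx(fit.params[1], abs=1e-6)
        ci = fit.conf_int()[1]
        assert math.log(lo) == pytest.approx(ci[0], abs=1e-5)
        assert math.log(hi) == pytest.approx(ci[1], abs=1e-5)

    def test_label_inversion_gives_reciprocal_or(self):
        x = np.r_[np.ones(13), np.zeros(19), np.ones(4), np.zeros(28)]
        y = np.r_[np.ones(32), np.zeros(32)]
        orr, *_ = fit_logistic_univariable(x, y)
        inv, *_ = fit_logistic_univariable(x, 1 - y)
        assert inv == pytest.approx(1.0 / orr, rel=1e-6)

    def test_permuted_labels_give_null_or_and_uniformish_p(self):
        rng = np.random.default_rng(7)
        x = np.r_[np.ones(30), np.zeros(34)]
        y = np.r_[np.ones(32), np.zeros(32)]
        log_ors, ps = [], []
        for _ in range(200):
            yp = rng.permutation(y)
            try:
                orr, _, _, p = fit_logistic_univariable(x, yp)
            except SeparationError:
                continue
            log_ors.append(math.log(orr))
            ps.append(p)
        assert abs(np.mean(log_ors)) < 0.15
        rej = np.mean(np.array(ps) <= 0.05)
        assert 0.0 <= rej <= 0.12

    def test_complete_separation_signalled(self):
        x = np.r_[np.full(5, 2.0), np.full(5, 1.0)]
        y = np.r_[np.ones(5), np.zeros(5)]
        with pytest.raises(SeparationError):
            fit_logistic_univariable(x, y)


class TestCombinedBiomarker:
    def test_rule_count_scoring(self):
        import pandas as pd

        ft = pd.DataFrame(
            {"gap1S2": [35.0, 10.0, 40.0], "gap4S2": [900.0, 900.0, 100.0]},
            index=["a", "b", "c"],
        )
        score = combined_biomarker(ft, [("gap1S2", 30.0), ("gap4S2", 862.0)])
        assert score.tolist() == [2.0, 1.0, 1.0]

    def test_single_rule_reduces_to_indicator(self):
        import pandas as pd

        ft = pd.DataFrame({"gap1S2": [35.0, 10.0, 40.0, 5.0]}, index=list("abcd"))
        score = combined_biomarker(ft, [("gap1S2", 30.0)])
        y = np.array([1, 0, 1, 0])
        assert empirical_auc(score.to_numpy(), y) == empirical_auc(
            (ft["gap1S2"] >= 30).astype(float).to_numpy(), y
        )

    def test_missing_feature_value_excluded(self):
        import pandas as pd

        ft = pd.DataFrame(
            {"gap1S2": [35.0, np.nan], "gap4S2": [900.0, 900.0]}, index=["a", "b"]
        )
        score = combined_biomarker(ft, [("gap1S2", 30.0), ("gap4S2", 862.0)])
        assert score["a"] == 2.0
        assert np.isnan(score["b"])

    def test_combined_rules_beat_each_single_rule(self):
        """With partially independent errors the two-rule count separates
        classes better than either dichotomized feature alone."""
        aucs = {"gap1S2": [], "gap4S2": [], "combined": []}
        for seed in range(8):
            traces, labels = generate_cohort(default_config(seed=300 + seed))
            ft = build_feature_table(traces)
            y = ft.index.map(labels.is_cancer).to_numpy()
            score = combined_biomarker(ft, [("gap1S2", 30.0), ("gap4S2", 862.0)])
            aucs["combined"].append(empirical_auc(score.to_numpy(), y))
            for f, c in (("gap1S2", 30.0), ("gap4S2", 862.0)):
                ind = (ft[f] >= c).astype(float).to_numpy()
                aucs[f].append(empirical_auc(ind, y))
        mean = {k: np.mean(v) for k, v in aucs.items()}
        assert mean["combined"] > mean["gap1S2"]
        assert mean["combined"] > mean["gap4S2"]


class TestScreening:
    def test_alpha_one_carries_all_features(self):
        traces, labels = generate_cohort(
            default_config(n_cancer=6, n_noncancer=6, seed=13)
        )
        ft = build_feature_table(traces)
        y = ft.index.map(labels.is_cancer).to_numpy()
        rep = screen_features(ft, y, alpha=1.0)
        assert rep.records["auc"].notna().all()
        assert rep.records["cutoff"].notna().sum() == len(rep.significant_roc)

    def test_separated_gap_features_rank_top(self):
        traces, labels = generate_cohort(default_config(seed=17))
        ft = build_feature_table(traces)
        y = ft.index.map(labels.is_cancer).to_numpy()
        rep = screen_features(ft, y, alpha=1.0)
        top10 = rep.records.index[:10]
        assert "gap1S2" in top10 or "gap4S2" in top10

    def test_forced_feature_enters_roc_stage(self):
        traces, labels = generate_cohort(default_config(seed=19))
        ft = build_feature_table(traces)
        y = ft.index.map(labels.is_cancer).to_numpy()
        rep = screen_features(ft, y, alpha=1e-9, forced=("min1S4",))
        assert not np.isnan(rep.records.loc["min1S4", "auc"])

    def test_bh_column_is_monotone_transform(self):
        traces, labels = generate_cohort(
            default_config(n_cancer=6, n_noncancer=6, seed=23)
        )
        ft = build_feature_table(traces)
        y = ft.index.map(labels.is_cancer).to_numpy()
        rep = screen_features(ft, y, bh_column=True)
        df = rep.records.sort_values("t_p")
        assert (df["t_p_bh"] >= df["t_p"] - 1e-12).all()
        assert df["t_p_bh"].is_monotonic_increasing
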