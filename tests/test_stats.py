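"""Statistics: closed-form oracles, exhaustive AUC checks, model recovery."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hcmstrain.stats import (
    anova_bonferroni,
    bland_altman,
    classify_rule,
    compare_aucs,
    compare_groups,
    fit_multilevel,
    hanley_mcneil_se,
    roc_analysis,
)


def _published_quadrant_cohort():
    """Subject-level metrics realizing the printed quadrant counts:
    carriers 11 positive / 7 SL-only / 2 negative / 8 DCSR-only,
    controls 0 / 3 / 18 / 7."""
    sl, dcsr, car = [], [], []

    def add(n, s, d, is_car):
        sl.extend([s] * n)
        dcsr.extend([d] * n)
        car.extend([is_car] * n)

    add(11, 1.3, 90.0, True)   # positive
    add(7, 1.3, 120.0, True)   # SL-only
    add(2, 1.1, 120.0, True)   # negative
    add(8, 1.1, 90.0, True)    # DCSR-only
    add(3, 1.3, 120.0, False)
    add(18, 1.1, 120.0, False)
    add(7, 1.1, 90.0, False)
    return np.array(sl), np.array(dcsr), np.array(car)


class TestComparison:
    def test_known_t_statistic(self):
        # closed form: equal n, classical pooled-variance t
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = x + 2.0
        r = compare_groups(x, y, force="t")
        sp = np.sqrt(((4 * x.var(ddof=1)) + (4 * y.var(ddof=1))) / 8)
        t_manual = (x.mean() - y.mean()) / (sp * np.sqrt(2 / 5))
        assert r.statistic == pytest.approx(t_manual)

    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        r = compare_groups(x, x.copy())
        assert r.p_value > 0.99

    def test_normality_gate_switches_to_mann_whitney(self):
        rng = np.random.default_rng(1)
        x = rng.exponential(size=80) ** 3  # grossly non-normal
        y = rng.exponential(size=80) ** 3
        assert compare_groups(x, y).test == "mann-whitney"
        z = rng.normal(size=80)
        assert compare_groups(z, z + 0.1).test == "t"

    def test_calibrated_sl_separation_is_usually_significant(self):
        from hcmstrain.cohort import carrier_group, control_group, truth_table, sample_cohort

        p05 = p01 = 0
        for seed in range(10):
            car = truth_table(sample_cohort(carrier_group(), 28, seed))
            ctl = truth_table(sample_cohort(control_group(), 28, 1000 + seed))
            r = compare_groups(car.sl_ratio, ctl.sl_ratio)
            p05 += r.p_value < 0.05
            p01 += r.p_value < 0.01
        assert p05 >= 8 and p01 >= 5


class TestROC:
    def test_hanley_mcneil_printed_value(self):
        assert round(hanley_mcneil_se(0.72, 28, 28), 2) == 0.07

    def test_se_shrinks_with_n_at_fixed_auc(self):
        ses = [hanley_mcneil_se(0.72, n, n) for n in (10, 50, 250, 1250)]
        assert all(a > b for a, b in zip(ses, ses[1:]))
        assert ses[-1] < 0.02

    def test_se_matches_bootstrap_within_20_percent(self):
        rng = np.random.default_rng(2)
        y = np.r_[np.ones(50, bool), np.zeros(50, bool)]
        s = rng.normal(size=100) + 0.8 * y
        roc = roc_analysis(s, y)
        boot = []
        for _ in range(600):
            i = np.r_[rng.choice(np.where(y)[0], 50), rng.choice(np.where(~y)[0], 50)]
            boot.append(roc_analysis(s[i], y[i]).auc)
        assert roc.se_auc == pytest.approx(np.std(boot), rel=0.20)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(scores=st.lists(st.integers(-5, 5), min_size=4, max_size=12),
           data=st.data())
    def test_auc_equals_exhaustive_pairwise_fraction(self, scores, data):
        n = len(scores)
        n_pos = data.draw(st.integers(1, n - 1))
        y = np.zeros(n, bool)
        y[:n_pos] = True
        s = np.asarray(scores, float)
        roc = roc_analysis(s, y)
        wins = sum(
            (a > b) + 0.5 * (a == b)
            for a, b in itertools.product(s[y], s[~y])
        )
        assert roc.auc == pytest.approx(wins / (n_pos * (n - n_pos)), abs=1e-12)
        assert roc.auc == pytest.approx(np.trapezoid(roc.tpr, roc.fpr), abs=1e-12)

    def test_perfect_separation_and_one_class_error(self):
        y = np.r_[np.ones(5, bool), np.zeros(5, bool)]
        s = np.r_[np.arange(5) + 10.0, np.arange(5)]
        roc = roc_analysis(s, y)
        assert roc.auc == 1.0
        assert roc.sensitivity_pct == 100.0 and roc.specificity_pct == 100.0
        with pytest.raises(ValueError):
            roc_analysis(s, np.ones(10, bool))

    def test_direction_less_flips_orientation(self):
        y = np.r_[np.ones(5, bool), np.zeros(5, bool)]
        s = np.r_[np.arange(5), np.arange(5) + 10.0]  # positives score LOW
        assert roc_analysis(s, y, direction="less").auc == 1.0


class TestCompareAUCs:
    def test_identical_rocs_give_zero_z(self):
        rng = np.random.default_rng(3)
        y = np.r_[np.ones(20, bool), np.zeros(20, bool)]
        s = rng.normal(size=40) + y
        roc = roc_analysis(s, y)
        assert compare_aucs(roc, roc, r=1.0).z == 0.0

    def test_r_zero_reduces_to_independent_comparison(self):
        rng = np.random.default_rng(4)
        y = np.r_[np.ones(25, bool), np.zeros(25, bool)]
        r1 = roc_analysis(rng.normal(size=50) + y, y)
        r2 = roc_analysis(rng.normal(size=50) + 0.4 * y, y)
        c = compare_aucs(r1, r2, r=0.0)
        z = (r1.auc - r2.auc) / np.hypot(r1.se_auc, r2.se_auc)
        assert c.z == pytest.approx(z)

    def test_z_against_bootstrap_auc_difference_null(self):
        # paired scores: the analytic SE of the AUC difference should match
        # a subject-resampling bootstrap to ~30 %
        rng = np.random.default_rng(5)
        n = 40
        y = np.r_[np.ones(n, bool), np.zeros(n, bool)]
        base = rng.normal(size=2 * n)
        s1 = base + 0.9 * y + 0.4 * rng.normal(size=2 * n)
        s2 = base + 0.7 * y + 0.4 * rng.normal(size=2 * n)
        r1, r2 = roc_analysis(s1, y), roc_analysis(s2, y)
        c = compare_aucs(r1, r2)
        diffs = []
        pos, neg = np.where(y)[0], np.where(~y)[0]
        for _ in range(400):
            i = np.r_[rng.choice(pos, n), rng.choice(neg, n)]
            diffs.append(
                roc_analysis(s1[i], y[i]).auc - roc_analysis(s2[i], y[i]).auc
            )
        analytic_se = np.sqrt(
            r1.se_auc**2 + r2.se_auc**2 - 2 * c.r * r1.se_auc * r2.se_auc
        )
        assert analytic_se == pytest.approx(np.std(diffs), rel=0.35)


class TestClassification:
    def test_published_quadrants_ppv_and_npv(self):
        sl, dcsr, car = _published_quadrant_cohort()
        res = classify_rule(sl, dcsr, car)
        assert res.positive == {"carrier": 11, "control": 0}
        assert res.negative == {"carrier": 2, "control": 18}
        assert res.sl_only == {"carrier": 7, "control": 3}
        assert res.dcsr_only == {"carrier": 8, "control": 7}
        assert res.ppv_pct == 100.0
        assert res.npv_pct == pytest.approx(90.0)
        assert res.n_carriers == 28 and res.n_controls == 28

    def test_counts_sum_to_group_sizes_and_missing_excluded(self):
        sl, dcsr, car = _published_quadrant_cohort()
        sl = sl.astype(float)
        sl[0] = np.nan
        res = classify_rule(sl, dcsr, car)
        assert res.n_carriers == 27
        assert res.excluded == {"carrier": 1, "control": 0}

    def test_empty_positive_quadrant_gives_nan_ppv(self):
        res = classify_rule([1.0, 1.1], [120.0, 130.0], [True, False])
        assert np.isnan(res.ppv_pct)

    def test_label_swap_exchanges_sensitivity_and_specificity(self):
        sl, dcsr, car = _published_quadrant_cohort()
        a = classify_rule(sl, dcsr, car)
        b = classify_rule(sl, dcsr, ~car)
        assert b.sensitivity_pct == pytest.approx(100.0 - a.specificity_pct)
        assert b.specificity_pct == pytest.approx(100.0 - a.sensitivity_pct)


class TestAgreement:
    def test_identical_vectors(self):
        r = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.mean_difference == 0.0
        assert r.coefficient_of_variability == 0.0

    def test_constant_offset(self):
        r = bland_altman([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert r.mean_difference == 1.0
        assert r.sd_difference == 0.0
        assert r.loa_lower == r.loa_upper == 1.0

    def test_hand_computed_pairs(self):
        a = np.array([-18.0, -20.0, -17.0, -19.0])
        b = np.array([-17.5, -20.5, -17.2, -18.6])
        r = bland_altman(a, b)
        d = a - b
        assert r.mean_difference == pytest.approx(d.mean())
        assert r.sd_difference == pytest.approx(d.std(ddof=1))
        cov_manual = np.mean(np.abs(d) / np.sqrt(2) / np.abs((a + b) / 2))
        assert r.coefficient_of_variability == pytest.approx(cov_manual)


class TestMultilevel:
    @staticmethod
    def _segment_table(seed, b_car=-9.0, subj_sd=6.0, slice_sd=4.0, n_per=28):
        rng = np.random.default_rng(seed)
        rows = []
        for g, lab in ((0, "control"), (1, "carrier")):
            for i in range(n_per):
                u = rng.normal(0, subj_sd)
                age = rng.normal(38, 12)
                for sl in range(3):
                    us = rng.normal(0, slice_sd)
                    for _ in range(6 if sl < 2 else 4):
                        edwt = rng.normal(5.5, 1.0)
                        y = (115 + b_car * g - 0.1 * (age - 38)
                             - 3.0 * (edwt - 5.5) + u + us + rng.normal(0, 12))
                        rows.append(dict(subject_id=f"{lab}{i}", slice=sl,
                                         carrier=g, age=age, edwt=edwt, dcsr=y))
        return pd.DataFrame(rows)

    def test_zero_random_variance_matches_ols(self):
        import statsmodels.formula.api as smf

        df = self._segment_table(0, subj_sd=0.0, slice_sd=0.0)
        res = fit_multilevel(df, "dcsr", ["carrier", "age", "edwt"])
        ols = smf.ols("dcsr ~ carrier + age + edwt", df).fit()
        for term in ("carrier", "age", "edwt"):
            assert res.beta(term) == pytest.approx(ols.params[term], abs=0.3)

    def test_known_effect_recovered_within_ci(self):
        df = self._segment_table(1)
        res = fit_multilevel(df, "dcsr", ["carrier", "age", "edwt"])
        lo, hi = res.ci95("carrier")
        assert lo <= -9.0 <= hi
        assert res.converged
        assert res.subject_variance > 0

    def test_permuted_labels_give_null_effect(self):
        df = self._segment_table(2)
        rng = np.random.default_rng(0)
        perm = dict(zip(df.subject_id.unique(),
                        rng.permutation(df.groupby("subject_id").carrier.first())))
        df["carrier"] = df.subject_id.map(perm)
        res = fit_multilevel(df, "dcsr", ["carrier", "age", "edwt"])
        lo, hi = res.ci95("carrier")
        assert lo <= 0.0 <= hi

    def test_interaction_screen_reports_all_pairs(self):
        df = self._segment_table(3, n_per=10)
        res = fit_multilevel(df, "dcsr", ["carrier", "age", "edwt"],
                             screen_interactions=True)
        assert len(res.interactions) == 3
        assert res.interactions.p.notna().all()


class TestAnova:
    def test_adjustment_identity_and_k2(self):
        rng = np.random.default_rng(6)
        v = rng.normal(size=60)
        g = np.repeat(["a", "b", "c"], 20)
        out = anova_bonferroni(v, g)
        assert len(out) == 3
        assert np.allclose(out.p_adj, np.minimum(1.0, 3 * out.p_raw))
        out2 = anova_bonferroni(v[:40], g[:40])  # k=2: single unadjusted test
        assert out2.p_adj.iloc[0] == pytest.approx(out2.p_raw.iloc[0])

    def test_type_i_error_controlled_under_equal_means(self):
        rng = np.random.default_rng(7)
        rejections = 0
        reps = 300
        for _ in range(reps):
            v = rng.normal(size=45)
            g = np.repeat(["a", "b", "c"], 15)
            out = anova_bonferroni(v, g)
            rejections += out.significant.any()
        # family-wise error at alpha=0.05 with Bonferroni: <= ~5 %
        assert rejections / reps < 0.09
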