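"""qPCR relative quantification, QC, ANOVA/LSD, t-tests, fold-changes, ELISA."""

import math

import numpy as np
import pytest
from scipy import stats

from mirshare.expression import (
    anova_lsd,
    boxplot_summary,
    elisa_normalize,
    group_fold_change,
    relative_expression,
    round_half_up,
    spike_in_qc,
    two_sample_t,
)


class TestRelativeExpression:
    def test_calibrator_identity_is_one(self):
        ratio = relative_expression(25.0, 20.0, 2.0, 2.0, calibrator_cts=(25.0, 20.0))
        assert ratio == pytest.approx(1.0)

    def test_one_cycle_doubling(self):
        # target one cycle earlier than the calibrator => twice the expression
        ratio = relative_expression(24.0, 20.0, 2.0, 2.0, calibrator_cts=(25.0, 20.0))
        assert ratio == pytest.approx(2.0)

    def test_unequal_efficiencies_match_arbitrary_precision_oracle(self):
        import sympy

        ratio = relative_expression(
            ct_target=22.7, ct_ref=19.6, E_target=1.9, E_ref=2.0,
            calibrator_cts=(25.0, 20.0),
        )  # delta_t = 2.3, delta_r = 0.4
        oracle = (sympy.Rational(19, 10) ** sympy.Rational(23, 10)
                  / sympy.Integer(2) ** sympy.Rational(4, 10)).evalf(30)
        assert ratio == pytest.approx(float(oracle), rel=1e-12)

    def test_reduces_to_ddct_when_efficiencies_are_two(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            ct_t, ct_r, cal_t, cal_r = rng.uniform(15, 35, 4)
            ratio = relative_expression(ct_t, ct_r, 2.0, 2.0, (cal_t, cal_r))
            ddct = (ct_t - cal_t) - (ct_r - cal_r)
            assert ratio == pytest.approx(2.0 ** (-ddct), rel=1e-12)

    def test_undetectable_target_is_missing_not_zero(self):
        ratio = relative_expression(41.2, 20.0, 2.0, 2.0, (25.0, 20.0))
        assert math.isnan(ratio)

    def test_bad_efficiency_rejected(self):
        with pytest.raises(ValueError):
            relative_expression(25, 20, 1.0, 2.0, (25, 20))
        with pytest.raises(ValueError):
            relative_expression(25, 20, 2.0, 2.3, (25, 20))


class TestSpikeInQc:
    def test_equal_cts_all_pass(self):
        qc = spike_in_qc({f"s{i}": 22.0 for i in range(5)})
        assert qc["qc_pass"].all()

    def test_gross_outlier_flagged(self):
        cts = {f"s{i}": 22.0 + 0.05 * i for i in range(8)}
        cts["bad"] = 27.0
        qc = spike_in_qc(cts)
        flagged = set(qc.loc[~qc.qc_pass, "sample_id"])
        assert flagged == {"bad"}

    def test_fewer_than_three_samples_skips_with_warning(self):
        with pytest.warns(UserWarning):
            qc = spike_in_qc({"s1": 22.0, "s2": 30.0})
        assert qc["qc_pass"].all()

    def test_injected_outliers_flagged_at_expected_rate(self):
        rng = np.random.default_rng(8)
        caught = 0
        trials = 200
        for _ in range(trials):
            cts = {f"s{i}": rng.normal(22, 0.2) for i in range(11)}
            cts["out"] = 22 + 5  # 25 SD away
            caught += not spike_in_qc(cts).set_index("sample_id").loc["out", "qc_pass"]
        assert caught / trials > 0.95


class TestAnovaLsd:
    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = rng.normal(0, 1, 8)
            b = rng.normal(0.5, 1, 11)
            comp = anova_lsd({"a": a, "b": b})
            t, _ = two_sample_t(a, b)
            assert comp.F == pytest.approx(t * t, rel=1e-10)

    def test_matches_reference_f_computation(self):
        rng = np.random.default_rng(2)
        groups = {g: rng.normal(m, 1, 9) for g, m in (("x", 0), ("y", 1), ("z", 0.5))}
        comp = anova_lsd(groups)
        f_ref, p_ref = stats.f_oneway(*groups.values())
        assert comp.F == pytest.approx(float(f_ref), rel=1e-12)
        assert comp.p_overall == pytest.approx(float(p_ref), rel=1e-12)

    def test_small_worked_dataset(self):
        # k=3 groups of 3; grand mean 4; SSB = 3*((2-4)^2+(4-4)^2+(6-4)^2) = 24
        # SSW = 6; F = (24/2)/(6/6) = 12; LSD se = sqrt(1*(1/3+1/3))
        groups = {"g1": [1, 2, 3], "g2": [3, 4, 5], "g3": [5, 6, 7]}
        comp = anova_lsd(groups)
        assert comp.F == pytest.approx(12.0)
        se = math.sqrt(2 / 3)
        t12 = 2 / se
        assert comp.pairwise_p[("g1", "g2")] == pytest.approx(
            2 * stats.t.sf(t12, 6), rel=1e-12)

    def test_lsd_is_unadjusted(self):
        groups = {"a": [1.0, 2.0], "b": [1.1, 2.1], "c": [10.0, 11.0]}
        comp = anova_lsd(groups)
        # pairwise p for the near-identical pair stays large; no correction applied
        assert comp.pairwise_p[("a", "b")] > 0.5
        assert comp.pairwise_p[("a", "c")] < 0.01

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            anova_lsd({"a": [1, 1], "b": [1, 1]})
        with pytest.raises(ValueError):
            anova_lsd({"a": [1, 2]})
        with pytest.raises(ValueError):
            anova_lsd({"a": [1, 2], "b": [3]})


class TestTwoSampleT:
    def test_identical_arms_t_zero_p_one(self):
        t, p = two_sample_t([1, 2, 3], [1, 2, 3])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_large_shift_p_tiny(self):
        rng = np.random.default_rng(3)
        t, p = two_sample_t(rng.normal(5, 1, 200), rng.normal(0, 1, 200))
        assert p < 1e-20

    def test_matches_pooled_variance_formula(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 7), rng.normal(1, 2, 12)
        t, p = two_sample_t(a, b)
        sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (
            len(a) + len(b) - 2)
        t_ref = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
        assert t == pytest.approx(t_ref, rel=1e-12)
        assert p == pytest.approx(2 * stats.t.sf(abs(t_ref), len(a) + len(b) - 2),
                                  rel=1e-12)

    def test_paired_mode(self):
        a = [1.0, 2.0, 3.0, 4.0]
        b = [0.5, 1.8, 2.9, 3.1]
        t, p = two_sample_t(a, b, paired=True)
        ref = stats.ttest_rel(a, b)
        assert (t, p) == pytest.approx((ref.statistic, ref.pvalue))
        with pytest.raises(ValueError):
            two_sample_t(a, b[:3], paired=True)


class TestFoldChange:
    @pytest.mark.parametrize(
        "means, num, den, round_to, expected",
        [
            ({"glioma": 5.7, "PD": 2.0}, "glioma", "PD", 2, 2.85),
            ({"glioma": 5.7, "control": 1.76}, "glioma", "control", 2, 3.24),
            ({"tumor": 1.6, "peritumoral": 1.1}, "tumor", "peritumoral", 2, 1.45),
            ({"tumor": 0.08, "peritumoral": 0.036}, "tumor", "peritumoral", 1, 2.2),
            ({"a": 3.0, "b": 3.0}, "a", "b", 2, 1.0),
        ],
    )
    def test_reported_group_mean_ratios(self, means, num, den, round_to, expected):
        fc = group_fold_change(means, num, den, round_to=round_to)
        assert fc.reported == expected
        assert fc.value == pytest.approx(means[num] / means[den])

    def test_rounding_is_half_up(self):
        assert round_half_up(2.845, 2) == 2.85
        assert round_half_up(1.25, 1) == 1.3

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(ValueError):
            group_fold_change({"a": 1.0, "b": 0.0}, "a", "b")


class TestElisa:
    def test_planted_means_give_reported_fold(self):
        # per-sample pg/ng values whose compartment means are 0.08 and 0.036
        tumor = [0.06, 0.08, 0.10]
        peri = [0.03, 0.036, 0.042]
        means = {"tumor": float(np.mean(tumor)), "peritumoral": float(np.mean(peri))}
        assert group_fold_change(means, "tumor", "peritumoral", round_to=1).reported == 2.2

    def test_normalization_dimensional_analysis(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            conc = float(rng.uniform(10, 500))  # pg/mL
            vol = float(rng.uniform(0.05, 0.2))  # mL
            protein = float(rng.uniform(100, 1000))  # ng
            m = elisa_normalize(conc, vol, protein)
            assert m.normalized_pg_per_ng == pytest.approx(conc * vol / protein)
            assert m.in_range

    def test_zero_concentration_flagged_below_range(self):
        m = elisa_normalize(0.0, 0.1, 500.0)
        assert m.normalized_pg_per_ng == 0.0
        assert not m.in_range

    def test_invalid_protein_rejected(self):
        with pytest.raises(ValueError):
            elisa_normalize(100.0, 0.1, 0.0)


class TestBoxplotSummary:
    def test_tukey_whiskers_and_outliers(self):
        values = list(range(1, 10)) + [100.0]
        s = boxplot_summary(values)
        assert s["median"] == pytest.approx(5.5)
        assert s["outliers"] == [100.0]
        assert s["whisker_high"] == 9
        q1, q3 = np.percentile(values, [25, 75])
        assert (s["q1"], s["q3"]) == pytest.approx((q1, q3))
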