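"""Inference layer: effect sizes, noncentral-t CIs, ANOVA, Bayes factors,
correlations and power, checked against hand values and independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stopsig import inference
from stopsig.exceptions import StopsigError

HANDS = (229.36, 32.83, 30, 261.52, 39.00, 30)
FEET = (259.5, 41.6, 30, 276.74, 38.4, 30)


class TestEffectSize:
    @pytest.mark.parametrize("summ,expected", [(HANDS, 0.89), (FEET, 0.43)])
    def test_published_cohens_d(self, summ, expected):
        assert inference.pooled_cohens_d(*summ).d == pytest.approx(expected, abs=0.005)

    def test_identical_groups_give_zero(self):
        assert inference.pooled_cohens_d(100, 10, 20, 100, 10, 20).d == 0.0

    def test_zero_sd_rejected(self):
        with pytest.raises(StopsigError):
            inference.pooled_cohens_d(100, 0, 20, 110, 10, 20)


class TestTTest:
    @pytest.mark.parametrize("summ,expected", [(HANDS, 3.46), (FEET, 1.67)])
    def test_published_t_values(self, summ, expected):
        res = inference.independent_t_test(*summ, side="positive")
        assert res.t == pytest.approx(expected, abs=0.005)
        assert res.df == 58

    def test_null_point(self):
        res = inference.independent_t_test(100, 10, 20, 100, 10, 20, side="positive")
        assert res.t == 0.0 and res.p == pytest.approx(0.5)


class TestSmdConfidenceInterval:
    def test_published_bounds(self):
        d_hands = inference.pooled_cohens_d(*HANDS)
        assert d_hands.ci_low == pytest.approx(0.362, abs=0.01)
        assert d_hands.ci_high == pytest.approx(1.423, abs=0.01)
        d_feet = inference.pooled_cohens_d(*FEET)
        assert d_feet.ci_low == pytest.approx(-0.08, abs=0.01)
        assert d_feet.ci_high == pytest.approx(0.943, abs=0.01)

    def test_symmetric_around_zero(self):
        lo, hi = inference.smd_confidence_interval(0.0, 25, 25)
        assert lo == pytest.approx(-hi, abs=1e-6)

    def test_tail_probabilities_at_bounds(self):
        """The noncentral-t tail probability at each bound matches (1 +- conf)/2."""
        d, n1, n2, conf = 0.7, 24, 31, 0.9
        lo, hi = inference.smd_confidence_interval(d, n1, n2, conf)
        c = np.sqrt(n1 * n2 / (n1 + n2))
        t = d * c
        assert stats.nct.cdf(t, n1 + n2 - 2, lo * c) == pytest.approx((1 + conf) / 2, abs=1e-6)
        assert stats.nct.cdf(t, n1 + n2 - 2, hi * c) == pytest.approx((1 - conf) / 2, abs=1e-6)

    def test_simulated_coverage(self):
        """95% noncentral-t intervals cover the true d = 0.5 at nominal rate."""
        rng = np.random.default_rng(7)
        n, true_d, reps = 30, 0.5, 10_000
        x = rng.standard_normal((reps, n))
        y = rng.standard_normal((reps, n)) + true_d
        sp = np.sqrt((x.var(axis=1, ddof=1) + y.var(axis=1, ddof=1)) / 2)
        d_hat = (y.mean(axis=1) - x.mean(axis=1)) / sp
        hits = 0
        for d in d_hat:
            lo, hi = inference.smd_confidence_interval(float(d), n, n, 0.95)
            hits += lo <= true_d <= hi
        assert hits / reps == pytest.approx(0.95, abs=0.01)


def _long_table(y, groups):
    n, m = y.shape
    return pd.DataFrame(
        {
            "participant_id": np.repeat(np.arange(n), m),
            "group": np.repeat(groups, m),
            "effector": np.tile(["hands", "feet"], n),
            "value": y.ravel(),
        }
    )


class TestMixedAnova:
    def test_additive_shift_kills_interaction(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal(20)
        y = np.column_stack([base, base + 10.0])
        groups = np.repeat(["a", "b"], 10)
        res = inference.mixed_anova_2x2(_long_table(y, groups), "value", "effector",
                                        "participant_id", "group")
        assert res["interaction"].F == pytest.approx(0.0, abs=1e-12)

    def test_between_f_equals_squared_pooled_t(self):
        """Algebraic oracle: the between-groups F equals t^2 computed on
        per-subject means across effectors."""
        rng = np.random.default_rng(1)
        y = rng.standard_normal((24, 2))
        groups = np.repeat(["a", "b"], 12)
        res = inference.mixed_anova_2x2(_long_table(y, groups), "value", "effector",
                                        "participant_id", "group")
        sm = y.mean(axis=1)
        t = stats.ttest_ind(sm[12:], sm[:12]).statistic
        assert res["group"].F == pytest.approx(t**2, rel=1e-10)

    def test_published_partial_eta_squared(self):
        assert inference.partial_eta_squared(7.89, 1, 58) == pytest.approx(0.120, abs=5e-4)

    def test_against_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        y = rng.standard_normal((30, 2)) + np.array([0.3, 0.0])
        y[15:] += 0.4
        groups = np.repeat(["a", "b"], 15)
        table = _long_table(y, groups)
        ours = inference.mixed_anova_2x2(table, "value", "effector", "participant_id", "group")
        theirs = pingouin.mixed_anova(
            table, dv="value", within="effector", subject="participant_id", between="group"
        ).set_index("Source")
        assert ours["group"].F == pytest.approx(theirs.loc["group", "F"], rel=1e-8)
        assert ours["effector"].F == pytest.approx(theirs.loc["effector", "F"], rel=1e-8)
        assert ours["interaction"].F == pytest.approx(theirs.loc["Interaction", "F"], rel=1e-8)
        assert ours["group"].partial_eta_sq == pytest.approx(theirs.loc["group", "np2"], rel=1e-8)

    def test_missing_cell_rejected(self):
        rng = np.random.default_rng(3)
        y = rng.standard_normal((6, 2))
        table = _long_table(y, np.repeat(["a", "b"], 3)).iloc[:-1]
        with pytest.raises(StopsigError):
            inference.mixed_anova_2x2(table, "value", "effector", "participant_id", "group")


class TestBayesFactor:
    def test_null_t_favors_null(self):
        bf = inference.jzs_bayes_factor(0.0, 30, 30)
        assert bf.bf10 < 1.0
        assert bf.bf01 * bf.bf10 == pytest.approx(1.0)

    def test_monotone_in_t_two_sided(self):
        bfs = [inference.jzs_bayes_factor(t, 30, 30).bf10 for t in (0.0, 0.5, 1.5, 2.5, 4.0)]
        assert all(a < b for a, b in zip(bfs, bfs[1:]))

    def test_monte_carlo_oracle_at_null(self):
        """Quadrature matches prior-simulation Monte-Carlo integration at t = 0."""
        rng = np.random.default_rng(11)
        delta = stats.cauchy(0, 0.707).rvs(size=1_000_000, random_state=rng)
        num = stats.nct.pdf(0.0, 58, delta * np.sqrt(15)).mean()
        oracle = num / stats.t.pdf(0.0, 58)
        bf = inference.jzs_bayes_factor(0.0, 30, 30)
        assert bf.bf10 == pytest.approx(oracle, rel=0.01)

    def test_robustness_sweep_consistency(self):
        t = 3.455
        sweep = inference.bf_robustness(t, 30, 30, [0.5, 0.707, 1.0], side="positive")
        assert all(r.bf10 > 30 for r in sweep)  # same grade of evidence throughout
        single = inference.bf_robustness(t, 30, 30, [0.707], side="positive")
        direct = inference.jzs_bayes_factor(t, 30, 30, 0.0, 0.707, "positive")
        assert single[0].bf10 == pytest.approx(direct.bf10, rel=1e-10)

    def test_occam_penalty_grows_with_prior_width(self):
        sweep = inference.bf_robustness(0.0, 30, 30, [0.3, 0.707, 1.5])
        bfs = [r.bf10 for r in sweep]
        assert all(a > b for a, b in zip(bfs, bfs[1:]))

    def test_one_sided_truncation_direction(self):
        pos = inference.jzs_bayes_factor(2.5, 30, 30, side="positive")
        neg = inference.jzs_bayes_factor(2.5, 30, 30, side="negative")
        assert pos.bf10 > 1.0 > neg.bf10

    def test_invalid_prior_scale_rejected(self):
        with pytest.raises(StopsigError):
            inference.jzs_bayes_factor(1.0, 30, 30, prior_scale=0.0)


class TestCorrelations:
    def test_published_one_sided_lower_bound(self):
        res = inference.pearson_ci(0.63, 60, 0.95, "one_sided")
        assert res.ci_low == pytest.approx(0.48, abs=0.005)
        assert res.ci_high == 1.0

    def test_published_two_sided_interval(self):
        res = inference.pearson_ci(0.67, 30, 0.95, "two_sided")
        assert res.ci_low == pytest.approx(0.41, abs=0.005)
        assert res.ci_high == pytest.approx(0.83, abs=0.005)

    def test_zero_r_symmetric(self):
        res = inference.pearson_ci(0.0, 40)
        assert res.ci_low == pytest.approx(-res.ci_high)

    def test_degenerate_r_rejected(self):
        with pytest.raises(StopsigError):
            inference.pearson_ci(1.0, 30)

    def test_published_correlation_comparison(self):
        z, p = inference.compare_independent_correlations(0.67, 30, 0.54, 30, "one_sided")
        assert p == pytest.approx(0.224, abs=0.001)

    def test_equal_correlations_null_point(self):
        z, p = inference.compare_independent_correlations(0.5, 30, 0.5, 30, "one_sided")
        assert z == 0.0 and p == pytest.approx(0.5)

    def test_two_sided_symmetric_under_swap(self):
        _, p1 = inference.compare_independent_correlations(0.7, 30, 0.4, 25)
        _, p2 = inference.compare_independent_correlations(0.4, 25, 0.7, 30)
        assert p1 == pytest.approx(p2)


class TestSampleSize:
    def test_minimality_contract(self):
        f, rho = 0.33, 0.5
        n = inference.sample_size_mixed_anova(f, rho=rho)
        assert inference.power_mixed_anova_between(f, n, rho=rho) >= 0.80
        assert inference.power_mixed_anova_between(f, n - 2, rho=rho) < 0.80

    def test_huge_effect_needs_minimal_design(self):
        assert inference.sample_size_mixed_anova(100.0) == 4

    def test_reference_scenario_yields_58(self):
        # f = 0.33, alpha .05, power .80, 2x2 design, repeated-measures rho 0.5
        assert inference.sample_size_mixed_anova(0.33, rho=0.5) == 58

    def test_power_against_simulation(self):
        """Noncentral-F power formula matches a direct simulation of the design."""
        f, rho, n_total = 0.33, 0.5, 58
        rng = np.random.default_rng(5)
        reps, half = 5000, n_total // 2
        subj = rng.standard_normal((reps, n_total, 1)) * np.sqrt(rho)
        eps = rng.standard_normal((reps, n_total, 2)) * np.sqrt(1 - rho)
        y = subj + eps
        y[:, half:, :] += 2 * f  # two equal groups: means at 0 and 2f give Cohen's f
        groups = np.repeat([0, 1], half)
        F, (df1, df2) = inference.split_plot_f_stats(y, groups)["between"]
        empirical = (F > stats.f.isf(0.05, df1, df2)).mean()
        analytic = inference.power_mixed_anova_between(f, n_total, rho=rho)
        assert empirical == pytest.approx(analytic, abs=0.03)
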