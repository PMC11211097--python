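import numpy as np
import pytest

from fociquant import (
    GroupSample,
    assess_normality,
    grade_stars,
    select_and_run,
)


class TestStars:
    @pytest.mark.parametrize(
        "p,grade",
        [
            (0.5, "ns"), (0.051, "ns"),
            (0.05, "*"), (0.049, "*"),
            (0.01, "**"), (0.001, "***"),
            (0.0001, "****"), (1e-5, "****"),
            (0.0, "****"), (1.0, "ns"),
        ],
    )
    def test_inclusive_thresholds(self, p, grade):
        assert grade_stars(p) == grade

    @pytest.mark.parametrize("p", [-0.1, 1.5])
    def test_out_of_range_is_error(self, p):
        with pytest.raises(ValueError):
            grade_stars(p)


class TestNormalityBattery:
    def test_gaussian_sample_passes_all_four(self):
        rng = np.random.default_rng(12)
        verdict = assess_normality(rng.normal(0, 1, 1000))
        assert verdict.gaussian
        assert set(verdict.per_test_p) == {
            "dagostino_pearson", "anderson_darling", "shapiro_wilk", "kolmogorov_smirnov",
        }
        assert all(0 <= p <= 1 for p in verdict.per_test_p.values())

    def test_lognormal_sample_fails(self):
        rng = np.random.default_rng(12)
        verdict = assess_normality(rng.lognormal(0, 1, 1000))
        assert not verdict.gaussian
        assert all(p <= 0.05 for p in verdict.per_test_p.values())

    def test_constant_sample_is_non_gaussian_with_warning(self):
        with pytest.warns(UserWarning, match="zero variance"):
            verdict = assess_normality(np.full(20, 5.0))
        assert not verdict.gaussian

    def test_small_sample_policy(self):
        with pytest.warns(UserWarning, match="too small"):
            assert not assess_normality(np.array([1.0, 2.0, 3.0, 4.5, 2.2])).gaussian
        with pytest.raises(ValueError):
            assess_normality(np.array([1.0, 2.0, 3.0]))

    def test_combination_rules(self):
        # a sample engineered so the four tests disagree: mild contamination
        rng = np.random.default_rng(81)
        x = np.concatenate([rng.normal(0, 1, 190), rng.normal(4.2, 0.1, 6)])
        verdicts = {
            rule: assess_normality(x, combine=rule).gaussian
            for rule in ("all", "majority", "any")
        }
        p = assess_normality(x).per_test_p
        n_pass = sum(v > 0.05 for v in p.values())
        assert verdicts["all"] == (n_pass == 4)
        assert verdicts["majority"] == (n_pass >= 3)
        assert verdicts["any"] == (n_pass >= 1)


class TestSelection:
    def two_gaussian_groups(self, delta=0.0, n=1000, seed=3):
        rng = np.random.default_rng(seed)
        return [
            GroupSample("treated", rng.normal(100 + delta, 30, n)),
            GroupSample("control", rng.normal(100, 30, n), is_control=True),
        ]

    def test_gaussian_pair_uses_one_tailed_t(self):
        comp = select_and_run(self.two_gaussian_groups(delta=50))
        assert comp.chosen_test == "t_one_tailed"
        assert comp.stars["treated vs control"] == "****"

    def test_identical_samples_are_ns(self):
        rng = np.random.default_rng(6)
        x = rng.normal(10, 2, 500)
        comp = select_and_run(
            [GroupSample("treated", x), GroupSample("control", x.copy(), is_control=True)]
        )
        assert comp.stars["treated vs control"] == "ns"
        assert comp.omnibus_p > 0.4

    def test_non_gaussian_pair_uses_mann_whitney(self):
        rng = np.random.default_rng(8)
        comp = select_and_run(
            [
                GroupSample("treated", rng.lognormal(0.5, 1, 400)),
                GroupSample("control", rng.lognormal(0, 1, 400), is_control=True),
            ]
        )
        assert comp.chosen_test == "mann_whitney_one_tailed"

    def test_three_gaussian_groups_use_anova_holm_sidak(self):
        rng = np.random.default_rng(9)
        groups = [
            GroupSample("control", rng.normal(100, 10, 200), is_control=True),
            GroupSample("low", rng.normal(105, 10, 200)),
            GroupSample("high", rng.normal(130, 10, 200)),
        ]
        comp = select_and_run(groups)
        assert comp.chosen_test == "anova_holm_sidak"
        assert set(comp.p_values) == {"low vs control", "high vs control"}
        assert comp.stars["high vs control"] == "****"

    def test_three_lognormal_groups_use_kruskal_wallis(self):
        rng = np.random.default_rng(10)
        groups = [
            GroupSample(lbl, rng.lognormal(mu, 1, 300), is_control=(lbl == "control"))
            for lbl, mu in (("control", 0.0), ("a", 0.1), ("b", 0.8))
        ]
        comp = select_and_run(groups)
        assert comp.chosen_test == "kruskal_wallis"
        assert "omnibus" in comp.p_values

    def test_chosen_test_invariant_under_group_permutation(self):
        groups = self.two_gaussian_groups(delta=20)
        a = select_and_run(groups)
        b = select_and_run(groups[::-1])
        assert a.chosen_test == b.chosen_test
        assert a.p_values == b.p_values

    def test_single_group_is_error(self):
        with pytest.raises(ValueError, match="2 groups"):
            select_and_run([GroupSample("only", np.arange(10.0))])

    def test_no_control_falls_back_two_sided_with_warning(self):
        rng = np.random.default_rng(13)
        groups = [
            GroupSample("a", rng.normal(0, 1, 100)),
            GroupSample("b", rng.normal(0, 1, 100)),
        ]
        with pytest.warns(UserWarning, match="control"):
            comp = select_and_run(groups)
        assert comp.chosen_test == "t_two_sided"

    def test_holm_sidak_adjustment_not_below_raw(self):
        from scipy import stats as sps
        rng = np.random.default_rng(14)
        groups = [
            GroupSample("control", rng.normal(100, 10, 150), is_control=True),
            GroupSample("g1", rng.normal(103, 10, 150)),
            GroupSample("g2", rng.normal(106, 10, 150)),
            GroupSample("g3", rng.normal(100, 10, 150)),
        ]
        comp = select_and_run(groups)
        control = groups[0]
        for g in groups[1:]:
            raw = sps.ttest_ind(g.values, control.values, alternative="greater").pvalue
            assert comp.p_values[f"{g.label} vs control"] >= raw - 1e-12

    def test_rank_tests_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(15)
        treated = rng.lognormal(0.4, 1, 200)
        control = rng.lognormal(0, 1, 200)
        comp_raw = select_and_run(
            [GroupSample("treated", treated), GroupSample("control", control, is_control=True)]
        )
        comp_log = select_and_run(
            [GroupSample("treated", np.log(treated)),
             GroupSample("control", np.log(control), is_control=True)]
        )
        # log-normal data become normal after log, so force the rank branch
        from scipy import stats as sps
        p_raw = sps.mannwhitneyu(treated, control, alternative="greater").pvalue
        p_log = sps.mannwhitneyu(np.log(treated), np.log(control), alternative="greater").pvalue
        assert p_raw == pytest.approx(p_log)
        assert comp_raw.chosen_test == "mann_whitney_one_tailed"
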