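"""ANOVA, Tukey HSD, null pseudo-group, and regression F test."""

import numpy as np
import pytest
from scipy import stats

from aggassay import (
    GroupedObservations,
    compare_with_null_group,
    continuous_predictor_anova,
    one_way_anova,
    tukey_hsd,
)
from aggassay.errors import (
    DegenerateCovariateError,
    DegenerateDataError,
    IncompatibilityError,
)


def brute_force_anova(groups):
    """Independent oracle: explicit sums-of-squares loops."""
    allv = [x for g in groups.values() for x in g]
    grand = sum(allv) / len(allv)
    ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups.values())
    ssw = sum(
        (x - sum(g) / len(g)) ** 2 for g in groups.values() for x in g
    )
    dfb, dfw = len(groups) - 1, len(allv) - len(groups)
    F = (ssb / dfb) / (ssw / dfw)
    return F, dfb, dfw, float(stats.f.sf(F, dfb, dfw))


class TestOneWayAnova:
    def test_matches_brute_force_sums_of_squares(self):
        groups = {"a": [0.0, 0.0, 1.0, 1.0], "b": [1.0, 1.0, 2.0, 2.0]}
        res = one_way_anova(GroupedObservations({k: np.array(v) for k, v in groups.items()}))
        F, dfb, dfw, p = brute_force_anova(groups)
        assert res.F == pytest.approx(F, abs=1e-12)
        assert (res.df_between, res.df_within) == (dfb, dfw)
        assert res.p == pytest.approx(p, abs=1e-12)

    def test_three_by_five_degrees_of_freedom(self, rng):
        groups = {s: rng.normal(size=5) for s in ("early", "late", "nonfeeding")}
        res = one_way_anova(GroupedObservations(groups))
        assert (res.df_between, res.df_within) == (2, 12)

    def test_identical_groups_give_F_zero(self):
        obs = GroupedObservations({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        res = one_way_anova(obs)
        assert res.F == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_shift_invariance_and_scale_invariance(self, rng):
        groups = {k: rng.normal(size=6) for k in "abc"}
        base = one_way_anova(GroupedObservations(groups)).F
        shifted = one_way_anova(
            GroupedObservations({k: v + 17.3 for k, v in groups.items()})
        ).F
        scaled = one_way_anova(
            GroupedObservations({k: v * 4.2 for k, v in groups.items()})
        ).F
        assert shifted == pytest.approx(base, rel=1e-9)
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_zero_within_variance_unequal_means(self):
        res = one_way_anova(GroupedObservations({"a": [1.0, 1.0], "b": [2.0, 2.0]}))
        assert res.infinite_F and np.isinf(res.F) and res.p == 0.0

    def test_fully_constant_data_rejected(self):
        with pytest.raises(DegenerateDataError):
            one_way_anova(GroupedObservations({"a": [1.0, 1.0], "b": [1.0, 1.0]}))

    def test_single_group_rejected(self):
        with pytest.raises(DegenerateDataError):
            one_way_anova(GroupedObservations({"a": [1.0, 2.0]}))

    @pytest.mark.parametrize(
        "sizes, expected_df",
        [
            ((17, 14, 15), (2, 43)),      # relatedness design
            ((29, 32, 19, 18, 21), (4, 114)),  # five populations
            ((7, 8, 4), (2, 16)),         # three species
        ],
    )
    def test_unbalanced_design_dfs(self, sizes, expected_df, rng):
        groups = {f"g{i}": rng.normal(size=n) for i, n in enumerate(sizes)}
        res = one_way_anova(GroupedObservations(groups))
        assert (res.df_between, res.df_within) == expected_df


class TestTukey:
    def test_two_groups_equals_pooled_t_test(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(0.7, 1, 11)
        res = tukey_hsd(GroupedObservations({"a": a, "b": b}))
        t_p = stats.ttest_ind(a, b, equal_var=True).pvalue
        assert res.p_value("a", "b") == pytest.approx(t_p, abs=1e-10)

    def test_matches_reference_implementation(self, rng):
        """Balanced 3x5 design vs statsmodels' studentized-range Tukey."""
        sm = pytest.importorskip("statsmodels.stats.multicomp")
        groups = {k: rng.normal(loc, 1, 5) for k, loc in zip("abc", (0, 0.5, 1.5))}
        res = tukey_hsd(GroupedObservations(groups))
        vals = np.concatenate(list(groups.values()))
        labels = [k for k in groups for _ in range(5)]
        ref = sm.pairwise_tukeyhsd(vals, labels)
        mine = [res.p_value(a, b) for (a, b) in (("a", "b"), ("a", "c"), ("b", "c"))]
        np.testing.assert_allclose(mine, ref.pvalues, atol=1e-6)

    def test_kramer_reduces_to_classical_when_balanced(self, rng):
        groups = {k: rng.normal(size=5) for k in "abc"}
        res = tukey_hsd(GroupedObservations(groups))
        anova = one_way_anova(GroupedObservations(groups))
        msw = anova.SS_within / anova.df_within
        # classical balanced Tukey: q = |diff| / sqrt(MSW / n)
        for pr in res.pairs:
            q = abs(pr.mean_difference) / np.sqrt(msw / 5)
            expected = stats.studentized_range.sf(q, 3, anova.df_within)
            assert pr.p_adjusted == pytest.approx(expected, abs=1e-12)

    def test_sign_of_difference(self, rng):
        a, b = rng.normal(0, 1, 5), rng.normal(3, 1, 5)
        res = tukey_hsd(GroupedObservations({"a": a, "b": b}))
        pr = res.pairs[0]
        assert pr.mean_difference == pytest.approx(a.mean() - b.mean())
        assert pr.ci_lower < pr.mean_difference < pr.ci_upper


class TestNullPseudoGroup:
    def test_csr_groups_not_distinguishable_from_null(self, null_n5, analysis_scheme):
        """Groups drawn from the CSR simulator rarely reject vs 'random'."""
        from aggassay import NullConfig, simulate_null_video, summarize_video

        rng = np.random.default_rng(2024)
        cfg = NullConfig(n_individuals=5)
        insignif = 0
        n_rep = 40
        for _ in range(n_rep):
            vals = [
                summarize_video(
                    simulate_null_video(cfg, rng), analysis_scheme
                ).log_mean_pairwise_distance
                for _ in range(8)
            ]
            res = compare_with_null_group(
                GroupedObservations({"obs": np.array(vals)}), null_n5
            )
            insignif += res.tukey.p_value("obs", "random") > 0.05
        assert insignif >= int(0.9 * n_rep)

    def test_shifted_groups_strongly_rejected(self, null_n5):
        """A group ln(2) below the null mean with n=15 videos is detected."""
        rng = np.random.default_rng(5)
        detected = 0
        n_rep = 30
        log_null_mean = float(null_n5.log_video_means.mean())
        sd = float(null_n5.log_video_means.std())
        for _ in range(n_rep):
            vals = rng.normal(log_null_mean - np.log(2), sd, 15)
            res = compare_with_null_group(
                GroupedObservations({"obs": vals}), null_n5
            )
            detected += res.tukey.p_value("obs", "random") < 0.001
        assert detected >= int(0.95 * n_rep)

    def test_classifications_reported_per_group(self, null_n5):
        lo, _ = null_n5.log_band
        res = compare_with_null_group(
            GroupedObservations({"tight": np.full(5, lo - 1.0)}), null_n5
        )
        assert res.classifications["tight"].label == "aggregative"
        assert res.anova.df_between == 1  # tight + random pseudo-group

    def test_empty_groups_rejected(self, null_n5):
        with pytest.raises(DegenerateDataError):
            GroupedObservations({})

    def test_reserved_label_collision(self, null_n5):
        obs = GroupedObservations({"random": np.array([1.0, 2.0])})
        with pytest.raises(IncompatibilityError):
            compare_with_null_group(obs, null_n5)


class TestContinuousPredictor:
    def test_latitude_design_degrees_of_freedom(self, rng):
        sizes = (29, 32, 19, 18, 21)  # 119 videos
        groups = {f"p{i}": rng.normal(size=n) for i, n in enumerate(sizes)}
        cov = {f"p{i}": np.full(n, 30.0 + 3 * i) + rng.normal(0, 0.1, n)
               for i, n in enumerate(sizes)}
        res = continuous_predictor_anova(GroupedObservations(groups, covariate=cov))
        assert (res.df_between, res.df_within) == (1, 117)

    def test_exact_linear_response(self):
        x = np.arange(10.0)
        y = 2.0 * x + 1.0
        obs = GroupedObservations({"all": y}, covariate={"all": x})
        res = continuous_predictor_anova(obs)
        assert res.p < 1e-12
        assert res.SS_within / res.SS_between < 1e-12  # R^2 = 1
        assert res.group_means["slope"] == pytest.approx(2.0)

    def test_matches_scipy_linregress(self, rng):
        x = rng.uniform(25, 45, 50)
        y = 1.8 + 0.01 * x + rng.normal(0, 0.2, 50)
        res = continuous_predictor_anova(
            GroupedObservations({"all": y}, covariate={"all": x})
        )
        lr = stats.linregress(x, y)
        assert res.F == pytest.approx(lr.rvalue**2 / (1 - lr.rvalue**2) * 48, rel=1e-9)
        assert res.p == pytest.approx(lr.pvalue, rel=1e-9)

    def test_type_one_error_near_nominal(self, rng):
        """Response independent of covariate: ~5% rejections at alpha=0.05."""
        n_rep, n = 400, 25
        rej = 0
        for _ in range(n_rep):
            x = rng.uniform(0, 1, n)
            y = rng.normal(size=n)
            res = continuous_predictor_anova(
                GroupedObservations({"all": y}, covariate={"all": x})
            )
            rej += res.p < 0.05
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rej / n_rep - 0.05) < 3 * se

    def test_constant_covariate_rejected(self):
        obs = GroupedObservations(
            {"all": np.array([1.0, 2.0, 3.0])},
            covariate={"all": np.array([5.0, 5.0, 5.0])},
        )
        with pytest.raises(DegenerateCovariateError):
            continuous_predictor_anova(obs)

    def test_missing_covariate_rejected(self):
        obs = GroupedObservations({"all": np.array([1.0, 2.0, 3.0])})
        with pytest.raises(DegenerateCovariateError):
            continuous_predictor_anova(obs)
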