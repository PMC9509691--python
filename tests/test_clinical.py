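"""Cohort metrics, two-sample tests, the synthetic cohort generator, and the comparison grid."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oph import (
    CohortParams,
    GroupParams,
    analyze_cohort,
    diff_ph,
    normalize_by_saliva,
    permutation_test,
    synth_cohort,
    welch_t_test,
)
from oph.clinical import EXHAUSTIVE_LIMIT, aggregate_readings


class TestElementaryMetrics:
    @pytest.mark.parametrize(
        "rest, drop, expected", [(7.0, 5.5, 1.5), (6.0, 6.0, 0.0), (6.0, 6.4, -0.4)]
    )
    def test_diff(self, rest, drop, expected):
        assert diff_ph(rest, drop) == pytest.approx(expected)

    def test_diff_missing_operand_is_missing(self):
        assert math.isnan(diff_ph(None, 5.5))
        assert math.isnan(diff_ph(6.0, float("nan")))

    def test_saliva_normalisation(self):
        assert normalize_by_saliva(7.0, 7.0) == pytest.approx(1.0)
        assert normalize_by_saliva(6.3, 7.0) == pytest.approx(0.9)
        assert math.isnan(normalize_by_saliva(6.3, float("nan")))
        with pytest.raises(ValueError):
            normalize_by_saliva(6.3, 0.0)


class TestWelch:
    def test_identical_groups(self):
        t, df, p = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_hand_computed_oracle(self):
        """Direct evaluation of the Welch formulas for a = (1,2,3), b = (1,2,3,4,5)."""
        a, b = np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        t_oracle = (a.mean() - b.mean()) / math.sqrt(va + vb)
        df_oracle = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
        t, df, p = welch_t_test(a, b)
        assert t == pytest.approx(t_oracle, rel=1e-12)  # -1.095445
        assert df == pytest.approx(df_oracle, rel=1e-12)  # 5.8846
        assert p == pytest.approx(2 * stats.t.sf(abs(t_oracle), df_oracle), rel=1e-9)

    def test_sign_flips_and_p_symmetric_under_swap(self):
        a, b = [1.0, 2.0, 4.0], [2.0, 3.0, 5.0, 6.0]
        t_ab, _, p_ab = welch_t_test(a, b)
        t_ba, _, p_ba = welch_t_test(b, a)
        assert t_ab == pytest.approx(-t_ba) and p_ab == pytest.approx(p_ba)

    def test_equal_variance_equal_n_reduces_to_student(self):
        a, b = [1.0, 2.0, 3.0, 4.0], [3.0, 4.0, 5.0, 6.0]
        t_w, df_w, p_w = welch_t_test(a, b)
        student = stats.ttest_ind(a, b, equal_var=True)
        assert t_w == pytest.approx(student.statistic) and df_w == pytest.approx(6.0)
        assert p_w == pytest.approx(student.pvalue)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0], [1.0, 2.0])


class TestPermutation:
    def test_exhaustive_two_vs_two(self):
        """All C(4,2)=6 label splits: only the observed split and its mirror reach |dmean| >= 9."""
        assert permutation_test([1.0, 2.0], [10.0, 11.0]) == pytest.approx(2.0 / 6.0)

    def test_constant_pool_gives_p_one(self):
        assert permutation_test([3.0, 3.0, 3.0], [3.0, 3.0]) == pytest.approx(1.0)

    def test_sampled_agrees_with_exhaustive_within_three_se(self):
        a = [1.2, 3.4, 2.2, 4.1]
        b = [2.0, 5.5, 4.4, 3.3, 6.1]
        p_exact = permutation_test(a, b, method="exhaustive")
        n_perm = 10_000
        p_sampled = permutation_test(a, b, n_perm=n_perm, seed=11, method="sampled")
        se = math.sqrt(p_exact * (1 - p_exact) / n_perm)
        assert abs(p_sampled - p_exact) <= 3 * se + 1.0 / (n_perm + 1)

    def test_sampled_reproducible_and_never_zero(self):
        rng_vals = list(np.linspace(0, 1, 30))
        other = list(np.linspace(5, 6, 30))
        p1 = permutation_test(rng_vals, other, n_perm=500, seed=9)
        p2 = permutation_test(rng_vals, other, n_perm=500, seed=9)
        assert p1 == p2
        assert p1 >= 1.0 / 501

    def test_custom_statistic_path(self):
        p = permutation_test(
            [1.0, 2.0], [10.0, 11.0], statistic=lambda a, b: abs(np.median(a) - np.median(b))
        )
        assert p == pytest.approx(2.0 / 6.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            permutation_test([], [1.0])

    def test_exhaustive_mode_triggers_below_limit(self):
        # 8 vs 8 -> C(16,8) = 12870 <= 20000: exact proportion, no +1 correction artifacts
        a = list(range(8))
        b = [x + 0.5 for x in range(8)]
        assert math.comb(16, 8) <= EXHAUSTIVE_LIMIT
        p_auto = permutation_test(a, b, seed=1)
        p_exh = permutation_test(a, b, method="exhaustive")
        assert p_auto == p_exh


class TestSynthCohort:
    def test_default_bookkeeping_matches_study_structure(self):
        cohort = synth_cohort(seed=5)
        assert len(cohort.readings) == 540
        n_rest = int(cohort.surfaces["rest_ph"].notna().sum())
        n_drop = int(cohort.surfaces["drop_ph"].notna().sum())
        assert (n_rest, n_drop) == (85, 95)
        assert len(cohort.subjects) == 25

    def test_zero_noise_replicates_equal_surface_mean(self):
        params = CohortParams(replicate_sd=0.0)
        cohort = synth_cohort(params, seed=2)
        merged = cohort.readings.merge(
            cohort.surfaces[["surface_id", "rest_ph", "drop_ph"]], on="surface_id"
        )
        for phase in ("rest", "drop"):
            sub = merged[merged["phase"] == phase]
            np.testing.assert_allclose(sub["ph"], sub[f"{phase}_ph"], atol=1e-12)

    def test_deterministic_under_seed(self):
        a = synth_cohort(seed=31)
        b = synth_cohort(seed=31)
        pd.testing.assert_frame_equal(a.readings, b.readings)
        pd.testing.assert_frame_equal(a.surfaces, b.surfaces)
        pd.testing.assert_frame_equal(a.subjects, b.subjects)

    def test_large_cohort_rank0_rest_mean_near_study_value(self):
        """Law of large numbers: rank-0 resting pH converges to the published 6.73 average."""
        groups = tuple(
            dataclasses.replace(g, n_surfaces=250, n_drop_only=0) for g in CohortParams().groups
        )
        cohort = synth_cohort(CohortParams(groups=groups), seed=8)
        rank0 = cohort.surfaces[cohort.surfaces["rank"] == 0]
        assert rank0["rest_ph"].mean() == pytest.approx(6.73, abs=0.1)

    def test_readings_within_trusted_range(self):
        cohort = synth_cohort(seed=17)
        assert cohort.readings["ph"].between(4.0, 7.5).all()

    def test_aggregate_readings_reconstructs_surface_table(self):
        cohort = synth_cohort(seed=23)
        rebuilt = aggregate_readings(cohort.readings)
        merged = cohort.surfaces.merge(rebuilt, on="surface_id", suffixes=("", "_rb"))
        np.testing.assert_allclose(merged["rest_ph"], merged["rest_ph_rb"], atol=1e-12)
        np.testing.assert_allclose(merged["drop_ph"], merged["drop_ph_rb"], atol=1e-12)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            GroupParams(name="g", n_subjects=0, n_surfaces=5, rest_mean=6.7, diff_mean=0.5)
        with pytest.raises(ValueError):
            CohortParams(replicate_sd=-0.1)


class TestAnalyzeCohort:
    def test_full_grid_shape_and_determinism(self):
        cohort = synth_cohort(seed=4)
        res1 = analyze_cohort(cohort.surfaces, cohort.subjects, n_perm=300, seed=1)
        res2 = analyze_cohort(cohort.surfaces, cohort.subjects, n_perm=300, seed=1)
        pd.testing.assert_frame_equal(res1, res2)
        # 3 metrics x 2 normalisations x (3 between-group cells + 2 within-group cells)
        assert len(res1) == 30
        assert list(res1["metric"].unique()) == ["rest", "drop", "diff"]

    def test_welch_suppressed_when_normality_fails(self):
        cohort = synth_cohort(seed=4)
        res = analyze_cohort(cohort.surfaces, cohort.subjects, n_perm=200, seed=1)
        not_normal = res[~res["normal_ok"]]
        assert not_normal["welch_p"].isna().all()
        normal = res[res["normal_ok"]]
        assert normal["welch_p"].notna().all()

    def test_single_group_keeps_within_group_comparison_only(self):
        params = CohortParams(
            groups=(
                GroupParams(
                    name="pre_cleaning",
                    n_subjects=5,
                    n_surfaces=40,
                    rest_mean=6.7,
                    diff_mean=0.8,
                    rank1_fraction=0.4,
                ),
            )
        )
        cohort = synth_cohort(params, seed=6)
        res = analyze_cohort(cohort.surfaces, cohort.subjects, n_perm=200, seed=0)
        assert set(res["comparison"]) == {"within_pre_cleaning_rank0_vs_rank1"}

    def test_detects_published_group_separation(self):
        """Default cohorts reproduce the study's diff-pH separation between groups:
        the effect points the right way, and the test detects it in most cohorts."""
        cohort = synth_cohort(seed=2024)
        res = analyze_cohort(cohort.surfaces, cohort.subjects, n_perm=2000, seed=1)
        row = res[
            (res["metric"] == "diff")
            & (res["normalization"] == "raw")
            & (res["comparison"] == "post_cleaning_vs_pre_cleaning")
        ].iloc[0]
        assert row["n_a"] == 45 and row["n_b"] == 40
        assert row["mean_b"] > row["mean_a"]  # pre-cleaning acidifies more

        # detection is stochastic per cohort; require a clear majority of seeds
        from oph import permutation_test

        hits = 0
        for seed in range(25):
            c = synth_cohort(seed=seed)
            diff = c.surfaces["rest_ph"] - c.surfaces["drop_ph"]
            a = diff[c.surfaces["group"] == "pre_cleaning"].dropna().to_numpy()
            b = diff[c.surfaces["group"] == "post_cleaning"].dropna().to_numpy()
            hits += permutation_test(a, b, n_perm=1000, seed=seed) < 0.05
        assert hits / 25 >= 0.7
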