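"""Family-clustered association models and surrounding analysis steps."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf
from hypothesis import given, settings
from hypothesis import strategies as st

from geekdex import assoc, gi, synth
from geekdex.errors import ConvergenceError, DomainError


def _independent_rows_cohort(n=600, seed=0):
    """Children in distinct families with no shared family effect: the
    mixed model must collapse to ordinary regression."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "family_id": np.arange(n),
            "x": rng.normal(size=n),
            "y": rng.normal(size=n),
        }
    ).assign(y=lambda d: 0.5 * d.x + rng.normal(size=n))


class TestFitLMM:
    def test_reduces_to_ols_without_clustering(self):
        df = _independent_rows_cohort()
        fit = assoc.fit_lmm("y", ["x"], df)
        ols = smf.ols("y ~ x", df).fit()
        assert abs(fit.beta("x") - ols.params["x"]) < 1e-4
        assert abs(fit.coefficients.loc["Intercept", "beta"] - ols.params["Intercept"]) < 1e-4

    def test_invariant_to_family_relabeling_and_row_order(self, small_cohort):
        fit1 = assoc.fit_lmm("gi_default", ["paternal_age"], small_cohort)
        relabeled = small_cohort.copy()
        relabeled["family_id"] = relabeled["family_id"] * 13 + 5
        relabeled = relabeled.sample(frac=1.0, random_state=1)
        fit2 = assoc.fit_lmm("gi_default", ["paternal_age"], relabeled)
        assert abs(fit1.beta("paternal_age") - fit2.beta("paternal_age")) < 1e-6
        assert abs(fit1.loglik - fit2.loglik) < 1e-4

    def test_rank_deficient_design_names_terms(self, small_cohort):
        df = small_cohort.copy()
        df["paternal_age_copy"] = df["paternal_age"]
        with pytest.raises(ValueError, match="paternal_age"):
            assoc.fit_lmm("gi_default", ["paternal_age", "paternal_age_copy"], df)

    def test_counts_and_pvalues(self, small_cohort):
        fit = assoc.fit_lmm("gi_default", ["paternal_age", *assoc.ADJUSTED_COVARIATES], small_cohort)
        assert fit.n_children == len(small_cohort)
        assert fit.n_families == small_cohort.family_id.nunique()
        assert ((fit.coefficients["p"] >= 0) & (fit.coefficients["p"] <= 1)).all()
        assert fit.random_intercept_var >= 0

    def test_paternal_age_effect_recovery_small(self):
        # 3 replicates at modest n; full-scale recovery lives in the
        # acceptance suite
        vals = []
        for s in range(3):
            cfg = dataclasses.replace(
                synth.SimConfig(), n_families=3000, beta_pa_male=0.28, beta_pa_female=0.28, seed=500 + s
            )
            df = gi.score_cohort(synth.simulate_cohort_frame(cfg), variants=("default",))
            vals.append(assoc.fit_lmm("gi_default", ["paternal_age"], df).beta("paternal_age"))
        assert abs(np.mean(vals) - 0.28) < 0.05


class TestLogisticMixed:
    def test_null_slope_gives_or_near_one(self):
        rng = np.random.default_rng(7)
        n = 2000
        df = pd.DataFrame(
            {
                "family_id": np.repeat(np.arange(n // 2), 2),
                "x": rng.normal(size=n),
                "y": rng.integers(0, 2, size=n),
            }
        )
        fit = assoc.fit_logistic_mixed("y", ["x"], df)
        row = fit.coefficients.loc["x"]
        assert row["or_low"] < 1.0 < row["or_high"]

    def test_or_recovery_per_gi_unit(self):
        # generating odds ratio 1.04 per GI unit on the top-2-STEM outcome
        ors = []
        for s in range(3):
            cfg = dataclasses.replace(synth.SimConfig(), n_families=3000, seed=600 + s)
            df = gi.score_cohort(synth.simulate_cohort_frame(cfg), variants=("default",))
            df["stem_top2"] = df["stem_top2"].astype(int)
            fit = assoc.fit_logistic_mixed("stem_top2", ["gi_default"], df)
            ors.append(float(fit.coefficients.loc["gi_default", "or_"]))
        assert abs(np.mean(ors) - 1.04) < 0.01

    def test_separation_raises_informative_error(self):
        n = 200
        df = pd.DataFrame(
            {
                "family_id": np.arange(n),
                "x": np.linspace(-2, 2, n),
            }
        )
        df["y"] = (df.x > 0).astype(int)  # perfectly separated
        with pytest.raises(ConvergenceError, match="separation"):
            assoc.fit_logistic_mixed("y", ["x"], df)


class TestQuadraticLRT:
    def test_delta_nonnegative_and_p_valid(self, small_cohort):
        delta, dof, p = assoc.lrt_quadratic(small_cohort)
        assert delta >= 0
        assert dof == 1
        assert 0 <= p <= 1

    def test_true_quadratic_detected(self):
        cfg = dataclasses.replace(synth.SimConfig(), n_families=2000, seed=8)
        df = gi.score_cohort(synth.simulate_cohort_frame(cfg), variants=("default",))
        # inject a strong curvature on the outcome scale
        pa_c = df.paternal_age - df.paternal_age.mean()
        df["gi_default"] = df["gi_default"] + 0.1 * pa_c**2
        delta, _, p = assoc.lrt_quadratic(df)
        assert p < 0.01


class TestSubscaleComparison:
    def test_table_layout_and_aggregation_gain(self, small_cohort):
        table = assoc.subscale_vs_gi_comparison(small_cohort)
        assert set(table.index) == {"gi", "nonverbal_iq", "cast_social", "cast_rrb"}
        assert table.loc["gi", "p"] <= 1.0

    def test_zero_loading_subscale_has_null_effect(self):
        cfg = dataclasses.replace(
            synth.SimConfig(),
            n_families=4000,
            beta_pa_male=0.3,
            beta_pa_female=0.3,
            subscale_loadings=(0.1, 0.05, 0.0),
            seed=10,
        )
        df = gi.score_cohort(synth.simulate_cohort_frame(cfg), variants=("default",))
        table = assoc.subscale_vs_gi_comparison(df, covariates=())
        row = table.loc["cast_rrb"]
        assert abs(row["beta"]) < 3 * row["se"] + 1e-3

    def test_gi_more_significant_than_subscales_usually(self):
        wins = 0
        for s in range(5):
            cfg = dataclasses.replace(synth.SimConfig(), n_families=3000, beta_pa_male=0.4, beta_pa_female=0.4, seed=700 + s)
            df = gi.score_cohort(synth.simulate_cohort_frame(cfg), variants=("default",))
            table = assoc.subscale_vs_gi_comparison(df, covariates=())
            subs = table.drop(index="gi")
            if table.loc["gi", "p"] <= subs["p"].min():
                wins += 1
        assert wins >= 3


class TestSensitivityFilters:
    def test_identity_when_no_father_above_cap(self, small_cohort):
        capped = small_cohort[small_cohort.paternal_age <= 49]
        out = assoc.sensitivity_filters(capped, max_paternal_age=50)
        pd.testing.assert_frame_equal(out, capped)

    def test_family_dropped_together(self, small_cohort):
        df = small_cohort.copy()
        fam = df.family_id.iloc[0]
        df.loc[df.family_id == fam, "paternal_age"] = 55.0
        out = assoc.sensitivity_filters(df, max_paternal_age=50)
        assert fam not in set(out.family_id)
        assert len(df) - len(out) >= 2

    def test_autism_exclusion_count_arithmetic(self, small_cohort):
        df = small_cohort.copy()
        df["autism_flag"] = False
        df.iloc[: 36, df.columns.get_loc("autism_flag")] = True
        out = assoc.sensitivity_filters(df, exclude_autism=True)
        assert len(out) == len(df) - 36

    def test_retained_rows_unchanged(self, small_cohort):
        out = assoc.sensitivity_filters(small_cohort, max_paternal_age=45, exclude_autism=True)
        pd.testing.assert_frame_equal(out, small_cohort.loc[out.index])


class TestAttainmentPoints:
    def test_empty_is_zero(self):
        assert assoc.attainment_points([]) == 0.0

    def test_top_gcse_grade(self):
        assert assoc.attainment_points([("A*", "GCSE")]) == 8.0

    def test_a_level_counts_double(self):
        assert assoc.attainment_points([("A*", "A-level")]) == 16.0

    def test_unknown_grade_rejected(self):
        with pytest.raises(DomainError, match="grade"):
            assoc.attainment_points([("Z", "GCSE")])

    @given(st.lists(st.tuples(st.sampled_from(sorted(assoc.DEFAULT_GRADE_POINTS)), st.sampled_from(["GCSE", "A-level"])), max_size=12))
    @settings(deadline=None, max_examples=40)
    def test_additive_and_permutation_invariant(self, records):
        total = assoc.attainment_points(records)
        assert total == sum(assoc.attainment_points([r]) for r in records)
        assert total == assoc.attainment_points(records[::-1])


class TestGeekClusterGroups:
    def test_constant_outcome_equal_means(self, small_cohort):
        df = small_cohort.copy()
        df["stem_gcses"] = 4
        df["art_gcses"] = 3
        table = assoc.geek_cluster_groups(df)
        populated = table[table.n > 0]
        assert (populated.mean_stem_gcses == 4).all()
        assert (populated.mean_art_gcses == 3).all()

    def test_empty_group_flagged_not_raised(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "nonverbal_iq": rng.integers(4, 8, 50),
                "cast_social": rng.integers(2, 5, 50),
                "cast_rrb": rng.integers(2, 5, 50),
                "stem_gcses": rng.integers(0, 8, 50),
                "art_gcses": rng.integers(0, 8, 50),
            }
        )
        table = assoc.geek_cluster_groups(df)
        assert (table.n >= 0).all()
        empties = table[table.n == 0]
        assert empties.mean_stem_gcses.isna().all()

    def test_geek_cluster_outscores_partial_profiles(self):
        # STEM counts increase in GI, which increases in all three
        # subscales (below the RRB fold): the full cluster must beat
        # the partial-profile groups
        cfg = dataclasses.replace(synth.SimConfig(), n_families=6000, stem_count_per_gi=0.04, seed=12)
        df = synth.simulate_cohort_frame(cfg)
        table = assoc.geek_cluster_groups(df)
        assert table.loc["geek", "n"] > 0
        assert table.loc["geek", "mean_stem_gcses"] > table.loc["high_iq_only", "mean_stem_gcses"]
        assert table.loc["geek", "mean_stem_gcses"] > table.loc["high_rrb_aloof_only", "mean_stem_gcses"]
        # art counts are generated independent of the subscales
        arts = table.loc[["geek", "high_iq_only", "sample_mean"], "mean_art_gcses"]
        assert arts.max() - arts.min() < 0.6
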