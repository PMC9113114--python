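"""Association-stage tests: design coding, model specs, mixed-model F tests
(cross-checked against an independent lme4/lmerTest fit), interaction
pruning, simple slopes, and Benjamini-Hochberg FDR control."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from cerebmotor.simulate import (
    simulate_grip_outcomes,
    simulate_linear_outcomes,
    simulate_saccade_outcomes,
)
from cerebmotor.stats import (
    ModelSpec,
    benjamini_hochberg,
    build_spec,
    center_age,
    fit_model,
    prune_interactions,
    simple_slopes,
)
from conftest import cohort_config
from cerebmotor.simulate import generate_cohort


class TestCenterAge:
    def test_two_member_group(self):
        t = pd.DataFrame({"group": ["TD", "TD"], "age": [10.0, 20.0]})
        out = center_age(t)
        assert list(out["age_c"]) == [-5.0, 5.0]

    def test_per_group_mean_is_zero(self, small_cohort):
        out = center_age(small_cohort)
        means = out.groupby("group")["age_c"].mean()
        assert np.allclose(means, 0.0)

    def test_single_member_group_centers_to_zero(self):
        t = pd.DataFrame({"group": ["TD", "ASD"], "age": [12.0, 25.0]})
        out = center_age(t)
        assert list(out["age_c"]) == [0.0, 0.0]


class TestBuildSpec:
    def test_grip_group_contrast_terms(self):
        spec = build_spec("behavior-group-grip", "log_cov")
        assert spec.level1 == ("hand",)
        assert set(spec.level2) == {"group", "sex", "age_c"}
        assert set(spec.interactions) == {"group:hand", "group:sex", "group:age_c"}

    def test_midline_volume_model_has_no_hemisphere_or_random_term(self):
        spec = build_spec("volume-group-midline", "volume")
        assert "hemisphere" not in spec.level1
        assert not spec.random_intercept

    def test_clinical_midline_is_plain_regression(self):
        spec = build_spec("brain-clinical-midline", "ados_css")
        assert not spec.random_intercept
        assert "sex:volume" in spec.interactions

    def test_brain_behavior_three_way_sets(self):
        grip = build_spec("brain-behavior-grip", "log_cov")
        assert "group:hand:volume" in grip.interactions
        sac = build_spec("brain-behavior-saccade", "mean_error")
        assert {"group:amplitude:volume", "group:direction:volume"} <= set(
            sac.interactions
        )

    def test_lateralized_family_rejects_midline_roi(self):
        with pytest.raises(ValueError, match="midline"):
            build_spec("volume-group-lateralized", "volume", roi="vermis_VI_VII")

    def test_interaction_without_main_effect_rejected(self):
        with pytest.raises(ValueError, match="main effect"):
            ModelSpec(outcome="y", level2=("group",), interactions=("group:sex",))


class TestBenjaminiHochberg:
    def test_worked_example(self):
        res = benjamini_hochberg([0.01, 0.02, 0.04, 0.20], q=0.05)
        assert res.rejected == (True, True, False, False)
        assert res.p_crit == pytest.approx(0.025)

    def test_all_ones_rejects_nothing(self):
        res = benjamini_hochberg([1.0, 1.0, 1.0])
        assert res.n_rejected == 0

    def test_single_small_p_rejected(self):
        res = benjamini_hochberg([0.01])
        assert res.rejected == (True,)

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([])

    @staticmethod
    def brute_force(p, q):
        """Largest rejection set over all candidate thresholds."""
        p = np.asarray(p)
        best = np.zeros(p.size, dtype=bool)
        for t in p:
            r = p <= t
            if t <= r.sum() * q / p.size and r.sum() > best.sum():
                best = r
        return best

    @settings(max_examples=300, deadline=None)
    @given(
        ps=st.lists(
            st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=10
        ),
        q=st.sampled_from([0.01, 0.05, 0.1, 0.25]),
    )
    def test_matches_brute_force_and_statsmodels(self, ps, q):
        res = benjamini_hochberg(ps, q=q)
        assert np.array_equal(res.rejected, self.brute_force(ps, q))
        sm_rej = multipletests(ps, alpha=q, method="fdr_bh")[0]
        assert np.array_equal(res.rejected, sm_rej)


@pytest.fixture(scope="module")
def grip_fit():
    pt = generate_cohort(cohort_config(100, 100, seed=21))
    data = simulate_grip_outcomes(pt, coefficients={"group": 0.4}, seed=22)
    spec = build_spec("behavior-group-grip", "log_cov")
    return spec, data, fit_model(spec, data)


class TestFitModel:
    def test_group_effect_recovered_within_2se(self, grip_fit):
        _, _, fitted = grip_fit
        row = fitted.terms.set_index("term").loc["group"]
        assert abs(row["beta"] - 0.4) < 2 * row["se"]

    def test_satterthwaite_df_between_levels(self, grip_fit):
        """Between-subject terms get ~participant df; within-subject terms
        get ~observation df."""
        _, _, fitted = grip_fit
        terms = fitted.terms.set_index("term")
        assert 150 < terms.loc["group", "df_den"] < 210
        assert terms.loc["hand", "df_den"] > 800

    def test_matches_lmerTest_anova(self, grip_fit, tmp_path):
        """Independent oracle: lme4 + lmerTest Satterthwaite F table."""
        spec, data, fitted = grip_fit
        csv = tmp_path / "d.csv"
        from cerebmotor.stats import encode_design

        encode_design(data).to_csv(csv, index=False)
        script = tmp_path / "check.R"
        script.write_text(
            textwrap.dedent(
                f"""
                suppressMessages(library(lmerTest))
                d <- read.csv("{csv}")
                m <- lmer(log_cov ~ hand_c + group_c + sex_c + age_c +
                          group_c:hand_c + group_c:sex_c + group_c:age_c +
                          (1 | participant_id), data = d, REML = TRUE)
                a <- anova(m, ddf = "Satterthwaite")
                write.csv(data.frame(term = rownames(a), F = a$`F value`,
                                     df = a$DenDF, p = a$`Pr(>F)`),
                          "{tmp_path}/anova.csv", row.names = FALSE)
                """
            )
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        r = pd.read_csv(tmp_path / "anova.csv")

        def canon(term: str) -> frozenset:
            parts = [p[:-2] if p.endswith("_c") else p for p in term.split(":")]
            return frozenset("age_c" if p == "age" else p for p in parts)

        mine = {canon(t): row for t, row in fitted.terms.set_index("term").iterrows()}
        assert len(mine) == len(r)
        for row in r.itertuples(index=False):
            ours = mine[canon(row.term)]
            assert ours["F"] == pytest.approx(row.F, rel=1e-3)
            assert ours["df_den"] == pytest.approx(row.df, rel=1e-2)
            assert ours["p"] == pytest.approx(row.p, abs=1e-4)

    def test_ols_fallback_for_nonhierarchical_spec(self, small_cohort):
        data = simulate_linear_outcomes(
            small_cohort,
            {"1": 2.0, "group": -0.1},
            outcome="volume",
            random_intercept_sd=0.0,
            seed=23,
        )
        spec = build_spec("volume-group-midline", "volume")
        fitted = fit_model(spec, data)
        assert fitted.method == "ols"
        assert fitted.terms["df_den"].nunique() == 1


class TestPruning:
    def test_spec_without_interactions_unchanged(self, small_cohort):
        data = simulate_grip_outcomes(small_cohort, seed=24)
        spec = ModelSpec(
            outcome="log_cov", level1=("hand",), level2=("group",), interactions=()
        )
        fitted = prune_interactions(spec, data)
        assert fitted.pruning_trace == []
        assert set(fitted.spec.fixed_terms) == {"hand", "group"}

    def test_strong_interaction_survives_pruning(self):
        pt = generate_cohort(cohort_config(150, 150, seed=25))
        data = simulate_grip_outcomes(
            pt, coefficients={"group:hand": 0.5}, seed=26
        )
        spec = build_spec("behavior-group-grip", "log_cov")
        fitted = prune_interactions(spec, data)
        assert "group:hand" in fitted.spec.interactions

    def test_hierarchy_respected_during_pruning(self):
        """A two-way term is never dropped while its three-way parent stays."""
        pt = generate_cohort(cohort_config(120, 120, seed=27))
        vol = pd.Series(np.random.default_rng(28).normal(15, 2, size=len(pt)))
        data = simulate_grip_outcomes(
            pt, coefficients={"group:hand:volume": 0.25}, volume=vol, seed=29
        )
        spec = build_spec("brain-behavior-grip", "log_cov")
        fitted = prune_interactions(spec, data)
        if "group:hand:volume" in fitted.spec.interactions:
            assert {"group:hand", "group:volume", "hand:volume"} <= set(
                fitted.spec.interactions
            )
        for step in fitted.pruning_trace:
            assert step["p"] >= 0.05

    def test_null_interactions_mostly_pruned(self, small_cohort):
        """Under a null generator each interaction survives only at roughly
        the 5% LRT level; over 20 runs all three surviving in many runs
        would indicate broken pruning."""
        kept = 0
        for seed in range(20):
            data = simulate_grip_outcomes(small_cohort, seed=400 + seed)
            spec = build_spec("behavior-group-grip", "log_cov")
            fitted = prune_interactions(spec, data)
            kept += len(fitted.spec.interactions)
        # 60 interaction-tests at ~5% retention: P(kept > 12) is negligible
        assert kept <= 12


class TestSimpleSlopes:
    def test_slope_difference_equals_interaction_beta(self, grip_fit):
        _, _, fitted = grip_fit
        slopes = simple_slopes(fitted, "age_c", "group")
        inter = fitted.params["group:age_c"]
        assert slopes[1].slope - slopes[0].slope == pytest.approx(inter, abs=1e-12)

    def test_zero_interaction_gives_equal_slopes(self, small_cohort):
        data = simulate_linear_outcomes(
            small_cohort,
            {"1": 0.0, "group": 0.2, "sex": 0.0, "age_c": -0.5},
            outcome="y",
            level1={"hand": ["left", "right"]},
            seed=31,
        )
        spec = ModelSpec(
            outcome="y",
            level1=("hand",),
            level2=("group", "age_c"),
            interactions=("group:age_c",),
        )
        fitted = fit_model(spec, data)
        slopes = simple_slopes(fitted, "age_c", "group")
        # true interaction is zero: slopes differ only by estimation noise
        assert abs(slopes[1].slope - slopes[0].slope) < 4 * slopes[1].se

    def test_group_specific_volume_slopes_recovered(self):
        """TD slope -1.0, ASD slope 0.0 on vermal volume vs saccade error."""
        pt = generate_cohort(cohort_config(250, 250, seed=32))
        rng = np.random.default_rng(33)
        vol = pd.Series(rng.normal(1.6, 0.2, size=len(pt)))
        data = simulate_saccade_outcomes(
            pt,
            coefficients={"volume": -1.0, "group:volume": 1.0},
            volume=vol,
            seed=34,
        )
        spec = build_spec("brain-behavior-saccade", "mean_error")
        fitted = fit_model(spec, data)
        slopes = {s.level: s for s in simple_slopes(fitted, "volume", "group")}
        assert abs(slopes["TD"].slope - (-1.0)) < 2 * slopes["TD"].se
        assert abs(slopes["ASD"].slope - 0.0) < 2 * slopes["ASD"].se

    def test_continuous_moderator_rejected(self, grip_fit):
        _, _, fitted = grip_fit
        with pytest.raises(ValueError, match="categorical"):
            simple_slopes(fitted, "group", "age_c")
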