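"""Substantive logistic model, Rubin's rules, MAR-vs-MNAR comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import patmix as pm
from patmix.pooling import rubin_pool


@pytest.fixture(scope="module")
def outcome_registry():
    om = pm.OutcomeModel(intercept=-3.8, stage=(0.2, 0.4, np.log(2.0)), age=0.9)
    cfg = pm.GeneratorConfig(n_patients=50_000, seed=41, outcome_model=om)
    return pm.generate_registry(cfg), om


class TestSubstantiveFit:
    def test_stage_d_log_or_recovery(self, outcome_registry):
        table, om = outcome_registry
        fit = pm.fit_substantive(table)
        est = fit.params["stage_D"]
        assert abs(est - np.log(2.0)) < 3 * fit.bse["stage_D"]

    def test_permuted_outcome_gives_null(self, outcome_registry):
        table, _ = outcome_registry
        perm = table.copy()
        perm["MORT"] = np.random.default_rng(1).permutation(perm["MORT"].to_numpy())
        fit = pm.fit_substantive(perm)
        for name in ("stage_B", "stage_C", "stage_D"):
            assert abs(fit.params[name]) < 3 * fit.bse[name]

    def test_row_order_invariance(self, outcome_registry):
        table, _ = outcome_registry
        a = pm.fit_substantive(table).params
        b = pm.fit_substantive(table.sample(frac=1.0, random_state=2)).params
        assert np.allclose(a, b, atol=1e-8)

    def test_full_covariate_set_reference_levels(self, outcome_registry):
        table, _ = outcome_registry
        fit = pm.fit_substantive(
            table,
            covariates=("stage", "AGE", "sex", "admission_type", "imd_quintile",
                        "charlson_band", "tumour_site"),
        )
        # reference levels absent from the design
        for absent in ("stage_A", "sex_F", "admission_type_elective",
                       "imd_quintile_1", "charlson_band_0", "tumour_site_colon"):
            assert absent not in fit.params.index
        assert "stage_D" in fit.params.index


class TestRubinPool:
    def test_hand_worked_example(self):
        """m=2, estimates (1, 2), SEs (0.5, 0.5):
        Qbar=1.5, W=0.25, B=0.5, T=0.25+1.5*0.5=1, pooled SE=1."""
        fits = [
            (pd.Series({"x": 1.0}), pd.Series({"x": 0.5})),
            (pd.Series({"x": 2.0}), pd.Series({"x": 0.5})),
        ]
        pooled = rubin_pool(fits).table.loc["x"]
        assert np.isclose(pooled["estimate"], 1.5)
        assert np.isclose(pooled["W"], 0.25)
        assert np.isclose(pooled["B"], 0.5)
        assert np.isclose(pooled["T"], 1.0)
        assert np.isclose(pooled["se"], 1.0)

    def test_identical_fits_degenerate_to_single_fit(self):
        fits = [(pd.Series({"x": 0.7}), pd.Series({"x": 0.2}))] * 5
        pooled = rubin_pool(fits).table.loc["x"]
        assert np.isclose(pooled["B"], 0.0)
        assert np.isclose(pooled["T"], pooled["W"])
        assert np.isclose(pooled["se"], 0.2)
        assert np.isinf(pooled["df"])

    def test_invariant_to_imputation_order(self):
        rng = np.random.default_rng(3)
        fits = [
            (pd.Series({"x": rng.normal()}), pd.Series({"x": abs(rng.normal()) + 0.1}))
            for _ in range(8)
        ]
        a = rubin_pool(fits).table
        b = rubin_pool(fits[::-1]).table
        pd.testing.assert_frame_equal(a, b)

    def test_mismatched_names_rejected(self):
        fits = [
            (pd.Series({"x": 1.0}), pd.Series({"x": 0.5})),
            (pd.Series({"y": 2.0}), pd.Series({"y": 0.5})),
        ]
        with pytest.raises(pm.ValidationError, match="names"):
            rubin_pool(fits)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.floats(-5, 5), st.floats(0.05, 3.0)
            ),
            min_size=2,
            max_size=12,
        )
    )
    def test_matches_brute_force_oracle(self, pairs):
        """Independently coded Rubin formulas agree to 1e-12."""
        fits = [(pd.Series({"x": e}), pd.Series({"x": s})) for e, s in pairs]
        pooled = rubin_pool(fits).table.loc["x"]
        m = len(pairs)
        ests = [e for e, _ in pairs]
        ses = [s for _, s in pairs]
        qbar = sum(ests) / m
        w = sum(s * s for s in ses) / m
        b = sum((e - qbar) ** 2 for e in ests) / (m - 1)
        t = w + (1 + 1 / m) * b
        assert abs(pooled["estimate"] - qbar) < 1e-12
        assert abs(pooled["W"] - w) < 1e-12
        assert abs(pooled["B"] - b) < 1e-12
        assert abs(pooled["T"] - t) < 1e-12

    def test_barnard_rubin_df_smaller_than_large_sample(self):
        fits = [
            (pd.Series({"x": 1.0}), pd.Series({"x": 0.5})),
            (pd.Series({"x": 1.4}), pd.Series({"x": 0.5})),
            (pd.Series({"x": 0.9}), pd.Series({"x": 0.5})),
        ]
        large = rubin_pool(fits).table.loc["x", "df"]
        small = rubin_pool(fits, df_method="barnard-rubin", complete_df=100).table.loc["x", "df"]
        assert small < large
        with pytest.raises(pm.ValidationError, match="complete_df"):
            rubin_pool(fits, df_method="barnard-rubin")


class TestCompareAssumptions:
    def test_reported_percentage_changes(self):
        """Relative change uses the MAR odds ratio as denominator."""
        mar = pm.PooledFit.from_odds_ratios(
            {"stage_B": (1.24, 1.14, 1.35), "stage_D": (2.48, 2.25, 2.73)}, "MAR"
        )
        mnar = pm.PooledFit.from_odds_ratios(
            {"stage_B": (1.15, 1.04, 1.26), "stage_D": (1.82, 1.66, 2.00)}, "MNAR"
        )
        rep = pm.compare_assumptions(mar, mnar)
        assert round(rep.table.loc["stage_B", "pct_change"], 1) == -7.3
        assert round(rep.table.loc["stage_D", "pct_change"], 1) == -26.6
        # MAR stage-D point estimate 2.48 lies outside the MNAR CI (1.66, 2.00)
        assert bool(rep.table.loc["stage_D", "mar_outside_mnar_ci"])
        assert not bool(rep.table.loc["stage_B", "mar_outside_mnar_ci"])
        assert rep.table["direction_agrees"].all()

    def test_identical_fits_give_zero_changes_and_no_flags(self):
        summary = {"x": (1.5, 1.2, 1.9)}
        mar = pm.PooledFit.from_odds_ratios(summary, "MAR")
        mnar = pm.PooledFit.from_odds_ratios(summary, "MNAR")
        rep = pm.compare_assumptions(mar, mnar)
        assert np.allclose(rep.table["pct_change"], 0.0)
        assert not rep.table["mar_outside_mnar_ci"].any()
        assert not rep.table["mnar_outside_mar_ci"].any()

    def test_label_collision_rejected(self):
        summary = {"x": (1.5, 1.2, 1.9)}
        a = pm.PooledFit.from_odds_ratios(summary, "MAR")
        b = pm.PooledFit.from_odds_ratios(summary, "MAR")
        with pytest.raises(pm.ValidationError, match="assumption"):
            pm.compare_assumptions(a, b)

    def test_render_contains_percentage_column(self):
        mar = pm.PooledFit.from_odds_ratios({"x": (2.0, 1.8, 2.2)}, "MAR")
        mnar = pm.PooledFit.from_odds_ratios({"x": (1.5, 1.3, 1.7)}, "MNAR")
        text = pm.compare_assumptions(mar, mnar).render()
        assert "-25.0%" in text
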