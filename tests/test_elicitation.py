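"""Questionnaire validation, expert aggregation, Dirichlet moment matching."""

import numpy as np
import pandas as pd
import pytest

import patmix as pm
from patmix.elicitation import make_questionnaire_template, synthesize_questionnaire


def _uniform_questionnaire(expert_ids):
    rows = [
        {"expert_id": e, "cell": r, "stage": s, "probability": 0.25}
        for e in expert_ids
        for r in pm.CELLS
        for s in pm.STAGES
    ]
    return pd.DataFrame(rows)


class TestReadQuestionnaire:
    def test_single_uniform_expert_is_valid(self):
        rs = pm.read_questionnaire(_uniform_questionnaire(["e1"]))
        assert rs.K == 1
        assert len(rs.responses) == 16

    def test_six_expert_panel_counts(self):
        q = synthesize_questionnaire(
            pm.DEMO_ELICITED_MEANS, pm.DEMO_ELICITED_VARIANCES, n_experts=6, seed=1
        )
        rs = pm.read_questionnaire(q)
        assert rs.K == 6
        assert len(rs.responses) == 96

    def test_row_sum_breach_names_expert_and_cell(self):
        q = _uniform_questionnaire(["e1"])
        q.loc[(q["cell"] == 2) & (q["stage"] == "D"), "probability"] = 0.31  # sum 1.06
        with pytest.raises(pm.ValidationError, match="e1.*cell 2|cell 2.*e1"):
            pm.read_questionnaire(q)

    def test_duplicate_entries_rejected(self):
        q = _uniform_questionnaire(["e1"])
        q = pd.concat([q, q.iloc[[0]]], ignore_index=True)
        with pytest.raises(pm.ValidationError, match="duplicate"):
            pm.read_questionnaire(q)

    def test_probability_outside_unit_interval_rejected(self):
        q = _uniform_questionnaire(["e1"])
        q.loc[0, "probability"] = 1.2
        with pytest.raises(pm.ValidationError, match=r"\[0, 1\]"):
            pm.read_questionnaire(q)

    def test_csv_roundtrip(self, tmp_path):
        q = _uniform_questionnaire(["e1", "e2"])
        q.to_csv(tmp_path / "q.csv", index=False)
        rs = pm.read_questionnaire(tmp_path / "q.csv")
        assert rs.K == 2


class TestAggregateExperts:
    def test_two_expert_hand_arithmetic(self):
        """pi = mean, V = sample variance with divisor K-1 = 1."""
        a = {"A": 0.2, "B": 0.3, "C": 0.4, "D": 0.1}
        b = {"A": 0.4, "B": 0.3, "C": 0.2, "D": 0.1}
        rows = [
            {"expert_id": e, "cell": r, "stage": s, "probability": v[s]}
            for e, v in (("e1", a), ("e2", b))
            for r in pm.CELLS
            for s in pm.STAGES
        ]
        prior = pm.aggregate_experts(pm.read_questionnaire(pd.DataFrame(rows)))
        assert np.allclose(prior.pi.loc[1], [0.3, 0.3, 0.3, 0.1], atol=1e-12)
        assert np.allclose(prior.var.loc[1], [0.02, 0.0, 0.02, 0.0], atol=1e-12)

    def test_single_expert_rejected(self):
        rs = pm.read_questionnaire(_uniform_questionnaire(["e1"]))
        with pytest.raises(pm.ValidationError, match="2 experts"):
            pm.aggregate_experts(rs)

    def test_identical_experts_give_zero_variance_then_fit_fails(self):
        rs = pm.read_questionnaire(_uniform_questionnaire(["e1", "e2", "e3"]))
        prior = pm.aggregate_experts(rs)
        assert (prior.var == 0).all().all()
        with pytest.raises(pm.ValidationError, match="variance_floor"):
            pm.fit_dirichlet(prior)
        spec = pm.fit_dirichlet(prior, variance_floor=1e-3)
        assert (spec.gamma > 0).all().all()

    def test_rows_renormalised_to_simplex(self, demo_prior):
        assert np.allclose(demo_prior.pi.sum(axis=1), 1.0, atol=1e-12)


class TestFitDirichlet:
    def test_symmetric_case_s_equals_3(self):
        # Var = 0.25 * 0.75 / (S + 1) with S = 3 gives 0.046875
        prior = pm.ElicitedPrior.from_arrays(
            [[0.25] * 4] * 4, [[0.046875] * 4] * 4, K=2
        )
        spec = pm.fit_dirichlet(prior)
        assert np.allclose(spec.s_per_category, 3.0, atol=1e-10)
        assert np.allclose(spec.gamma, 0.75, atol=1e-10)

    def test_dead_under70_cell_hand_computed(self, demo_spec):
        """Moment formulas for the 'dead, age <= 70' panel, checked by hand:
        S = pi(1-pi)/V - 1 = (46.5, 69.55, 116.8, 239), E[S] = 117.9625."""
        assert np.allclose(
            demo_spec.s_per_category.loc[2], [46.5, 69.55, 116.8, 239.0], atol=1e-10
        )
        assert np.isclose(demo_spec.s_mean.loc[2], 117.9625, atol=1e-10)
        assert np.allclose(
            demo_spec.gamma.loc[2], [5.898125, 20.053625, 44.82575, 47.185], atol=1e-9
        )

    def test_mean_identity(self, demo_spec, demo_prior):
        assert np.allclose(demo_spec.mean(), demo_prior.pi, atol=1e-10)

    def test_variance_at_least_bernoulli_rejected(self):
        prior = pm.ElicitedPrior.from_arrays(
            [[0.25] * 4] * 4, [[0.2] * 4] * 4, K=2
        )
        with pytest.raises(pm.ValidationError, match="non-positive"):
            pm.fit_dirichlet(prior)

    def test_boundary_mean_rejected(self):
        with pytest.raises(pm.ValidationError, match="inside"):
            pm.ElicitedPrior.from_arrays(
                [[0.0, 0.4, 0.3, 0.3]] * 4, [[0.01] * 4] * 4, K=2
            )

    def test_moment_round_trip_by_simulation(self, demo_spec, demo_prior):
        """Dirichlet(gamma_r) draws reproduce the elicited means and the
        closed-form variance pi(1-pi)/(E[S]+1)."""
        rng = np.random.default_rng(99)
        n = 200_000
        for r in pm.CELLS:
            gamma = demo_spec.gamma.loc[r].to_numpy()
            draws = rng.dirichlet(gamma, size=n)
            pi = demo_prior.pi.loc[r].to_numpy()
            s = demo_spec.s_mean.loc[r]
            target_var = pi * (1 - pi) / (s + 1.0)
            mc_se = np.sqrt(target_var / n)
            assert np.all(np.abs(draws.mean(axis=0) - pi) < 3 * mc_se)
            assert np.all(np.abs(draws.var(axis=0) - target_var) < 0.1 * target_var)

    def test_scaling_variances_down_increases_confidence(self, demo_prior):
        spec1 = pm.fit_dirichlet(demo_prior)
        smaller = pm.ElicitedPrior.from_arrays(demo_prior.pi, demo_prior.var / 2.0, K=6)
        spec2 = pm.fit_dirichlet(smaller)
        assert (spec2.s_mean > spec1.s_mean).all()

    def test_aggregator_options(self, demo_prior):
        mean_spec = pm.fit_dirichlet(demo_prior, aggregator="mean")
        med_spec = pm.fit_dirichlet(demo_prior, aggregator="median")
        prec_spec = pm.fit_dirichlet(demo_prior, aggregator="precision")
        for spec in (mean_spec, med_spec, prec_spec):
            ratios = spec.gamma.div(spec.gamma.sum(axis=1), axis=0)
            assert np.allclose(ratios, demo_prior.pi, atol=1e-10)
        assert not np.allclose(mean_spec.s_mean, med_spec.s_mean)
        with pytest.raises(pm.ValidationError, match="aggregator"):
            pm.fit_dirichlet(demo_prior, aggregator="mode")

    def test_json_roundtrip(self, demo_spec):
        again = pm.DirichletSpec.from_json(demo_spec.to_json())
        assert np.allclose(again.gamma, demo_spec.gamma, atol=1e-12)


class TestTemplateAndSynthesis:
    def test_template_embeds_mar_panel(self, mar_stack, tmp_path):
        cells = pm.cell_probabilities(mar_stack)
        template = make_questionnaire_template(cells, tmp_path / "template.csv")
        assert len(template) == 16
        assert (template["mar_probability"] == cells.rounded(2).stack().to_numpy()).all()
        assert (tmp_path / "template.csv").exists()

    def test_synthetic_panel_approximates_target_moments(self):
        q = synthesize_questionnaire(
            pm.DEMO_ELICITED_MEANS, pm.DEMO_ELICITED_VARIANCES, n_experts=40, seed=2
        )
        prior = pm.aggregate_experts(pm.read_questionnaire(q))
        # mean of 40 experts has SE ~ sqrt(V/40) <= 0.034
        assert (prior.pi - pm.DEMO_ELICITED_MEANS).abs().max().max() < 0.1
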