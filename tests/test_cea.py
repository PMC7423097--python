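"""ICER arithmetic, dominance classification, and sensitivity analyses."""

import dataclasses

import numpy as np
import pytest

import oacost as oc
from oacost.costing import Category, Domain


class TestPercentReduction:
    @pytest.mark.parametrize("pre, post, expected", [
        (5.7, 3.2, 44.0),  # digital-arm pain reduction
        (5.2, 4.1, 21.0),  # face-to-face arm
        (4.0, 4.0, 0.0),
    ])
    def test_reported_values(self, pre, post, expected):
        assert oc.percent_reduction(pre, post) == expected

    def test_exact_value_available(self):
        assert oc.percent_reduction(5.7, 3.2, integer=False) == pytest.approx(
            2.5 / 5.7 * 100)

    def test_zero_baseline_rejected(self):
        with pytest.raises(oc.ValidationError):
            oc.percent_reduction(0.0, 0.0)


class TestICER:
    def test_headline_ratio_truncates_toward_zero(self):
        result = oc.icer(2_776, 10_611, 3.2, 4.1)
        assert result.delta_cost == pytest.approx(-7_835)
        assert result.delta_effect == pytest.approx(-0.9)
        assert result.ratio == pytest.approx(-7_835 / -0.9)
        assert result.reported == 8_705  # 8705.55... truncated, not rounded
        assert result.quadrant is oc.Quadrant.DOMINANT

    def test_equal_arms_have_undefined_ratio(self):
        result = oc.icer(500.0, 500.0, 3.0, 3.0)
        assert result.delta_cost == 0.0
        assert result.delta_effect == 0.0
        assert result.ratio is None
        assert result.reported is None

    @pytest.mark.parametrize("dc, de, quadrant", [
        (-1.0, -0.5, oc.Quadrant.DOMINANT),     # cheaper, less pain
        (1.0, 0.5, oc.Quadrant.DOMINATED),      # costlier, more pain
        (1.0, -0.5, oc.Quadrant.TRADEOFF_NE),   # costlier, less pain
        (-1.0, 0.5, oc.Quadrant.TRADEOFF_SW),   # cheaper, more pain
        (-1.0, 0.0, oc.Quadrant.DOMINANT),      # effect tie: by cost sign
        (1.0, 0.0, oc.Quadrant.DOMINATED),
    ])
    def test_quadrant_classification(self, dc, de, quadrant):
        assert oc.icer(100 + dc, 100.0, 3 + de, 3.0).quadrant is quadrant

    def test_change_from_baseline_variant(self):
        a = oc.EffectEstimate(5.7, 3.2)   # change -2.5
        b = oc.EffectEstimate(5.2, 4.1)   # change -1.1
        printed = oc.icer_from_estimates(2_776, 10_611, a, b)
        assert printed.reported == 8_705
        change = oc.icer_from_estimates(2_776, 10_611, a, b, measure="change")
        assert change.delta_effect == pytest.approx(-1.4)
        assert change.ratio == pytest.approx(-7_835 / -1.4)

    def test_effect_scores_validated(self):
        with pytest.raises(oc.ValidationError):
            oc.EffectEstimate(11.0, 3.0)


class TestOneWayDSA:
    @staticmethod
    def _total_cost(boa, ctx):
        def evaluate(params):
            ctx2 = dataclasses.replace(
                ctx, population_gross_hourly_wage=params["population_wage"])
            transport = dataclasses.replace(
                boa.transport, round_trip_minutes=params["round_trip_minutes"])
            spec2 = dataclasses.replace(boa, transport=transport)
            return oc.cost_model(spec2, ctx2).total
        return evaluate

    def test_degenerate_range_has_zero_span(self, boa, ctx):
        evaluate = self._total_cost(boa, ctx)
        base = {"population_wage": ctx.population_gross_hourly_wage,
                "round_trip_minutes": boa.transport.round_trip_minutes}
        wage = base["population_wage"]
        table = oc.one_way_dsa(evaluate, base, {"population_wage": (wage, wage)})
        assert table.loc[0, "span"] == 0.0

    def test_removing_transport_drops_exactly_the_transport_line(self, boa, ctx):
        evaluate = self._total_cost(boa, ctx)
        base = {"population_wage": ctx.population_gross_hourly_wage,
                "round_trip_minutes": boa.transport.round_trip_minutes}
        table = oc.one_way_dsa(evaluate, base, {
            "round_trip_minutes": (0.0, base["round_trip_minutes"])})
        breakdown = oc.cost_model(boa, ctx)
        transport_line = next(
            it.total for it in breakdown.items
            if it.domain is Domain.PATIENT
            and it.category is Category.TRANSPORTATION)
        row = table.iloc[0]
        assert row["output_base"] - row["output_low"] == pytest.approx(
            transport_line)

    def test_support_halved_vs_removed_differ_by_half_the_line(self, boa, ctx):
        full = oc.technical_support_unit_cost(
            boa.support.annual_budget, boa.support.annual_patients)

        def evaluate(params):
            support = oc.SupportSpec(annual_budget=params["support_budget"],
                                     annual_patients=boa.support.annual_patients,
                                     halved=boa.support.halved)
            return oc.cost_model(
                dataclasses.replace(boa, support=support), ctx).total

        base = {"support_budget": boa.support.annual_budget}
        table = oc.one_way_dsa(evaluate, base, {
            "support_budget": (0.0, boa.support.annual_budget)})
        row = table.iloc[0]
        # halved rule is in force, so removing the budget removes half of full
        assert row["output_base"] - row["output_low"] == pytest.approx(full / 2)

    def test_non_bracketing_range_rejected(self, boa, ctx):
        evaluate = self._total_cost(boa, ctx)
        base = {"population_wage": 100.0, "round_trip_minutes": 50.0}
        with pytest.raises(oc.ValidationError):
            oc.one_way_dsa(evaluate, base, {"population_wage": (150.0, 200.0)})


class TestPSA:
    @staticmethod
    def evaluate(params):
        delta_cost = params["cost_ja"] - params["cost_boa"]
        delta_effect = params["pain_ja"] - params["pain_boa"]
        return delta_cost, delta_effect

    DISTS = {
        "cost_ja": ("gamma", 2_776.0, 300.0),
        "cost_boa": ("gamma", 10_611.0, 1_000.0),
        "pain_ja": ("normal", 3.2, 0.5, 0.0, 10.0),
        "pain_boa": ("normal", 4.1, 0.5, 0.0, 10.0),
    }

    def test_zero_variance_reproduces_point_estimate(self):
        dists = {"cost_ja": ("gamma", 2_776.0, 0.0),
                 "cost_boa": ("fixed", 10_611.0),
                 "pain_ja": ("normal", 3.2, 0.0, 0.0, 10.0),
                 "pain_boa": ("normal", 4.1, 0.0, 0.0, 10.0)}
        result = oc.psa(dists, n_draws=20, seed=1, evaluate=self.evaluate)
        assert (result.draws["delta_cost"] == -7_835.0).all()
        assert np.allclose(result.draws["delta_effect"], -0.9)

    def test_seed_reproducibility(self):
        a = oc.psa(self.DISTS, n_draws=200, seed=42, evaluate=self.evaluate)
        b = oc.psa(self.DISTS, n_draws=200, seed=42, evaluate=self.evaluate)
        assert a.draws.equals(b.draws)
        assert a.ceac.equals(b.ceac)

    def test_means_converge_to_point_estimates(self):
        result = oc.psa(self.DISTS, n_draws=10_000, seed=7, evaluate=self.evaluate)
        se_cost = result.draws["delta_cost"].std(ddof=1) / np.sqrt(10_000)
        se_eff = result.draws["delta_effect"].std(ddof=1) / np.sqrt(10_000)
        assert abs(result.mean_delta_cost - (-7_835.0)) < 3 * se_cost
        assert abs(result.mean_delta_effect - (-0.9)) < 3 * se_eff

    def test_ceac_monotone_for_dominant_intervention(self):
        result = oc.psa(self.DISTS, n_draws=500, seed=3, evaluate=self.evaluate)
        probs = result.ceac["probability_cost_effective"].to_numpy()
        assert probs[0] > 0.99  # cheaper in essentially every draw
        assert probs.min() >= 0.0 and probs.max() <= 1.0

    def test_invalid_distribution_rejected(self):
        with pytest.raises(oc.ValidationError):
            oc.psa({"x": ("gamma", 10.0, -1.0)}, n_draws=5, seed=0,
                   evaluate=lambda p: (p["x"], 1.0))
        with pytest.raises(oc.ValidationError):
            oc.psa({"x": ("weird", 1.0)}, n_draws=5, seed=0,
                   evaluate=lambda p: (p["x"], 1.0))
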