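"""Accrual, discounting, intervention costing and incremental analysis."""

import numpy as np
import pytest

from markovcea import (
    CostingInputs,
    DiscountSpec,
    RewardSet,
    TransitionMatrix,
    ValidationError,
    accrue,
    classify_icer,
    compare,
    intervention_unit_cost,
    propagate,
    run_arms,
)


class TestDiscounting:
    def test_from_first_cycle_factors(self):
        d = DiscountSpec(rate=0.03, convention="from-first-cycle")
        assert d.factor(1) == pytest.approx(1 / 1.03)
        assert np.allclose(d.factors(3), [1.03**-1, 1.03**-2, 1.03**-3])

    def test_after_first_cycle_leaves_year_one_undiscounted(self):
        d = DiscountSpec(rate=0.03, convention="after-first-cycle")
        assert d.factor(1) == 1.0
        assert d.factor(2) == pytest.approx(1 / 1.03)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValidationError):
            DiscountSpec(rate=-0.01)


class TestAccrue:
    def test_single_cycle_control_qaly(self, matrix, rewards, all_severe):
        trace = propagate(all_severe, matrix, 1)
        res = accrue(trace, rewards, DiscountSpec(rate=0.03))
        assert res.qaly[0] == pytest.approx(0.4192, abs=1e-12)
        assert res.qaly_disc[0] == pytest.approx(0.4192 / 1.03, abs=1e-12)

    def test_eight_year_control_total(self, matrix, rewards, discount, all_severe):
        trace = propagate(all_severe, matrix, 8)
        res = accrue(trace, rewards, discount)
        assert round(res.total_qaly, 3) == 2.211

    def test_zero_rewards_give_zero_totals(self, states, matrix, all_severe, discount):
        zero = RewardSet(states, np.zeros(5), np.zeros(5))
        res = accrue(propagate(all_severe, matrix, 8), zero, discount)
        assert res.total_qaly == 0.0 and res.total_cost == 0.0

    def test_intervention_cost_charged_in_cycle_one(self, matrix, rewards, discount, all_severe):
        trace = propagate(all_severe, matrix, 8)
        base = accrue(trace, rewards, discount)
        charged = accrue(trace, rewards, discount, intervention_cost=128.0)
        extra = charged.cost_disc - base.cost_disc
        assert extra[0] == pytest.approx(128 / 1.03)
        assert np.allclose(extra[1:], 0.0)

    def test_state_space_mismatch_rejected(self, matrix, all_severe):
        from markovcea import StateSpace

        other = StateSpace(("a", "b", "c", "d", "death"), frozenset({"death"}))
        rw = RewardSet(other, np.array([0.5, 0.5, 0.5, 0.5, 0.0]), np.zeros(5))
        with pytest.raises(ValidationError):
            accrue(propagate(all_severe, matrix, 2), rw, DiscountSpec())

    def test_annuity_closed_form_with_full_health_no_mortality(self, states):
        """With utility 1 everywhere alive and no transitions out, the
        discounted QALY total is the plain annuity sum of factors."""
        m = TransitionMatrix(states, np.eye(5))
        rw = RewardSet(states, np.array([1.0, 1, 1, 1, 0]), np.zeros(5))
        d = DiscountSpec(rate=0.03)
        res = accrue(propagate(np.array([1.0, 0, 0, 0, 0]), m, 8), rw, d)
        assert res.total_qaly == pytest.approx(sum(1.03**-t for t in range(1, 9)))

    @pytest.mark.parametrize("rates", [(0.0, 0.03), (0.03, 0.05), (0.05, 0.10)])
    def test_discounted_total_decreases_with_rate(self, matrix, rewards, all_severe, rates):
        lo, hi = rates
        trace = propagate(all_severe, matrix, 8)
        assert (
            accrue(trace, rewards, DiscountSpec(rate=hi)).total_qaly
            < accrue(trace, rewards, DiscountSpec(rate=lo)).total_qaly
        )


class TestInterventionUnitCost:
    @pytest.mark.parametrize(
        "visits,hours,expected",
        [
            (3, 2.0, 125.75),  # occupational-therapy arm
            (12, 12.0, 539.0),  # multi-professional arm
            (0, 0.0, 26.0),  # aids only
        ],
    )
    def test_ingredient_costing(self, visits, hours, expected):
        c = CostingInputs(n_visits=visits, total_contact_hours=hours)
        assert intervention_unit_cost(c) == pytest.approx(expected)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValidationError):
            CostingInputs(n_visits=-1, total_contact_hours=1.0)


class TestCompare:
    def test_dominance_from_published_totals(self, matrix, rewards, discount, intervention, all_severe):
        _, _, cmpres = run_arms(matrix, rewards, discount, intervention, all_severe, 8)
        assert cmpres.verdict == "intervention dominates"
        assert cmpres.delta_qaly > 0 and cmpres.delta_cost < 0
        assert cmpres.icer is None and cmpres.threshold_class == "not-applicable"

    def test_identical_results_no_difference(self, matrix, rewards, discount, all_severe):
        trace = propagate(all_severe, matrix, 8)
        a = accrue(trace, rewards, discount, strategy="a")
        b = accrue(trace, rewards, discount, strategy="b")
        assert compare(a, b).verdict == "no difference"

    def test_icer_reported_when_costlier_and_better(self, matrix, rewards, discount, all_severe):
        trace = propagate(all_severe, matrix, 8)
        base = accrue(trace, rewards, discount)
        # same QALYs won't do: build a richer strategy by charging cost on top of better utility
        better = accrue(trace, rewards, discount, intervention_cost=1000.0)
        richer = type(better)(
            strategy="richer",
            qaly=better.qaly + 0.0125,
            cost=better.cost,
            life_years_per_cycle=better.life_years_per_cycle,
            qaly_disc=better.qaly_disc + 0.0125,
            cost_disc=better.cost_disc,
            life_years_disc=better.life_years_disc,
        )
        res = compare(richer, base)
        assert res.verdict == "icer"
        assert res.icer == pytest.approx(res.delta_cost / res.delta_qaly)

    def test_horizon_mismatch_rejected(self, matrix, rewards, discount, all_severe):
        a = accrue(propagate(all_severe, matrix, 8), rewards, discount)
        b = accrue(propagate(all_severe, matrix, 7), rewards, discount)
        with pytest.raises(ValidationError):
            compare(a, b)


class TestThresholds:
    @pytest.mark.parametrize(
        "icer,expected",
        [(10_000, "low"), (11_000, "low"), (30_000, "moderate"), (55_000, "moderate"), (70_000, "high"), (None, "not-applicable")],
    )
    def test_willingness_to_pay_bands(self, icer, expected):
        assert classify_icer(icer) == expected
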