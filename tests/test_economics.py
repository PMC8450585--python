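"""Discounted accumulation and the ICER dominance frontier."""

from dataclasses import replace

import numpy as np
import pytest

from lncea import (
    STRATEGIES,
    EconomicSettings,
    EconResult,
    ParameterError,
    accumulate,
    build_model,
    icer_frontier,
    net_monetary_benefit,
    simulate,
)
from lncea.economics import STATUS_EXTENDED, STATUS_FRONTIER, STATUS_STRONG, frontier_table
from lncea.model_builder import MarkovModel, Strategy, ExpandedState


def _single_state_model(utility: float, cost: float = 0.0) -> MarkovModel:
    strat = STRATEGIES["S1"]
    state = ExpandedState("Only", "maintenance", None, 1, frozenset({"in_cr"}))
    dead = ExpandedState("Death", "terminal", None, 1, frozenset({"dead"}))
    P = np.array([[1.0, 0.0], [0.0, 1.0]])
    return MarkovModel(strat, [state, dead], P,
                       np.array([utility, 0.0]), np.array([cost, 0.0]),
                       np.zeros(2))


def _res(label: str, cost: float, qaly: float) -> EconResult:
    strat = Strategy(label, STRATEGIES[label].induction_drug, STRATEGIES[label].maintenance_drug)
    return EconResult(strat, cost, qaly, cost, qaly)


class TestAccumulate:
    def test_half_year_cycle_no_discount(self):
        m = _single_state_model(1.0)
        s = EconomicSettings(discount_per_cycle=0.0, horizon_cycles=1)
        trace = simulate(m, s)
        assert accumulate(trace, m, s).total_qaly == pytest.approx(0.5)

    def test_two_cycle_discounted_geometric_sum(self):
        # 0.8 utility x 0.5 y x (1.015^-1 + 1.015^-2) = 0.7823534...
        m = _single_state_model(0.8)
        s = EconomicSettings(discount_per_cycle=0.015, horizon_cycles=2)
        trace = simulate(m, s)
        expected = 0.8 * 0.5 * (1.015**-1 + 1.015**-2)
        r = accumulate(trace, m, s)
        assert r.total_qaly == pytest.approx(expected, abs=1e-12)
        assert r.total_qaly == pytest.approx(0.7823534, abs=1e-7)
        assert r.undiscounted_qaly == pytest.approx(0.8)

    def test_dead_cohort_accrues_nothing(self, params):
        m = build_model(STRATEGIES["S1"], params)
        P = np.zeros_like(m.transition)
        P[:, m.state_index("Death")] = 1.0
        m.transition = P
        trace = simulate(m, params.settings, horizon_cycles=10)
        r = accumulate(trace, m, params.settings)
        assert r.total_qaly == pytest.approx(0.0)
        assert r.total_cost == pytest.approx(0.0)

    def test_discounted_below_undiscounted(self, params):
        m = build_model(STRATEGIES["S3"], params)
        trace = simulate(m, params.settings)
        r = accumulate(trace, m, params.settings)
        assert r.total_qaly < r.undiscounted_qaly
        assert r.total_cost < r.undiscounted_cost
        assert r.total_qaly <= params.settings.horizon_cycles * 0.5

    def test_life_expectancy_identity(self, params):
        """With utility 1 everywhere alive and no discounting, QALYs equal
        0.5 x expected cycles alive."""
        m = build_model(STRATEGIES["S6"], params)
        m.utility = (~m.tagged("dead")).astype(float)
        m.cycle_cost = np.zeros(m.n_states)
        m.entry_cost = np.zeros(m.n_states)
        s = replace(params.settings, discount_per_cycle=0.0)
        trace = simulate(m, s)
        r = accumulate(trace, m, s)
        alive = 1.0 - trace.occupancy[1:, m.state_index("Death")]
        assert r.total_qaly == pytest.approx(0.5 * alive.sum())

    def test_one_time_entry_cost_charged_on_entry_flow(self, params):
        m = build_model(STRATEGIES["S1"], params)
        trace = simulate(m, params.settings)
        base = accumulate(trace, m, params.settings).total_cost
        m.entry_cost = np.zeros(m.n_states)
        no_entry = accumulate(trace, m, params.settings).total_cost
        kt_entries = trace.entry_flow[:, m.state_index("Transplant")]
        assert base - no_entry == pytest.approx(
            float(
                ((1.015 ** -np.arange(1, trace.horizon + 1)) * kt_entries).sum()
                * params.costs.kt_entry_cost.value
            )
        )


class TestFrontier:
    def test_simple_icer(self):
        entries = icer_frontier([_res("S1", 100.0, 1.0), _res("S3", 200.0, 2.0)])
        by = {e.strategy.label: e for e in entries}
        assert by["S3"].icer == pytest.approx(100.0)
        assert by["S1"].status == STATUS_FRONTIER

    def test_strong_dominance(self):
        entries = icer_frontier([_res("S1", 100.0, 2.0), _res("S3", 200.0, 1.0)])
        by = {e.strategy.label: e for e in entries}
        assert by["S3"].status == STATUS_STRONG

    # published lifetime cumulative (cost, QALY) pairs
    LIFETIME = {
        "S1": (70_286, 9.745),
        "S2": (76_480, 10.702),
        "S3": (82_540, 14.287),
        "S4": (88_393, 14.866),
        "S5": (90_031, 14.869),
        "S6": (93_708, 15.517),
    }

    def test_published_lifetime_frontier_reproduced(self):
        entries = icer_frontier([_res(k, c, q) for k, (c, q) in self.LIFETIME.items()])
        by = {e.strategy.label: e for e in entries}
        assert {k for k, e in by.items() if e.status != STATUS_FRONTIER} == {"S2", "S4", "S5"}
        assert by["S3"].comparator.label == "S1"
        assert by["S3"].delta_qaly == pytest.approx(4.542, abs=1e-9)
        assert round(by["S3"].icer) == 2698
        # the unrounded S6-vs-S3 ratio lands at 9080 after rounding;
        # the published 9079 reflects unrounded internal totals
        assert by["S6"].comparator.label == "S3"
        assert round(by["S6"].icer) == 9080
        assert by["S6"].icer == pytest.approx(11_168 / 1.230, rel=1e-12)

    THREE_YEAR = {
        "S1": (15_874, 2.156),
        "S3": (15_972, 2.374),
        "S2": (17_469, 2.308),
        "S4": (17_484, 2.442),
        "S5": (17_594, 2.384),
        "S6": (18_897, 2.452),
    }

    def test_published_three_year_dominance_pattern(self):
        entries = icer_frontier([_res(k, c, q) for k, (c, q) in self.THREE_YEAR.items()])
        by = {e.strategy.label: e for e in entries}
        assert by["S2"].status == STATUS_STRONG
        assert by["S5"].status == STATUS_STRONG
        assert by["S3"].icer == pytest.approx(98 / 0.218)
        assert by["S4"].icer == pytest.approx(1512 / 0.068)

    def test_frontier_invariant_to_input_order(self):
        results = [_res(k, c, q) for k, (c, q) in self.LIFETIME.items()]
        a = icer_frontier(results)
        b = icer_frontier(list(reversed(results)))
        key = lambda es: [(e.strategy.label, e.status, e.icer) for e in es]
        assert key(a) == key(b)

    def test_removing_dominated_strategy_keeps_frontier_icers(self):
        full = icer_frontier([_res(k, c, q) for k, (c, q) in self.LIFETIME.items()])
        pruned = icer_frontier(
            [_res(k, c, q) for k, (c, q) in self.LIFETIME.items() if k not in ("S2", "S4", "S5")]
        )
        icers_full = {e.strategy.label: e.icer for e in full if e.status == STATUS_FRONTIER}
        icers_pruned = {e.strategy.label: e.icer for e in pruned}
        assert icers_full == icers_pruned

    def test_duplicate_strategies_rejected(self):
        with pytest.raises(ParameterError):
            icer_frontier([_res("S1", 1.0, 1.0), _res("S1", 2.0, 2.0)])

    def test_frontier_table_shape(self):
        df = frontier_table(icer_frontier([_res(k, c, q) for k, (c, q) in self.LIFETIME.items()]))
        assert list(df["strategy"]) == ["S1", "S2", "S3", "S4", "S5", "S6"]
        assert df.loc[df.strategy == "S3", "icer_rounded"].item() == 2698


class TestNMB:
    def test_values(self):
        assert net_monetary_benefit(_res("S1", 0.0, 1.0), 10_319) == pytest.approx(10_319)
        assert net_monetary_benefit(_res("S1", 10_319.0, 1.0), 10_319) == pytest.approx(0.0)
        with pytest.raises(ParameterError):
            net_monetary_benefit(_res("S1", 0.0, 1.0), -5.0)
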