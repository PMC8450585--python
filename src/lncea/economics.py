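"""Discounted cost/QALY accumulation and the incremental cost-effectiveness frontier.

QALYs are utility x time in state, with each 6-month cycle contributing half
a year.  Cycle ``t`` (1-based, state membership evaluated after the ``t``-th
transition) is discounted by ``(1 + r)^-t`` with ``r`` the per-cycle rate;
no half-cycle correction is applied.

The frontier logic implements both dominance kinds: *strong* dominance
(costlier and no more effective than another strategy) and *extended*
dominance (bypassed because a later frontier point buys QALYs at a lower
incremental price).  ICERs are reported unrounded; display rounding to whole
dollars is left to the caller.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort_engine import CohortTrace
from .model_builder import MarkovModel, Strategy
from .parameters import EconomicSettings, ParameterError


@dataclass(frozen=True)
class EconResult:
    """Discounted (and undiscounted) totals for one strategy."""

    strategy: Strategy
    total_cost: float
    total_qaly: float
    undiscounted_cost: float
    undiscounted_qaly: float

    @property
    def label(self) -> str:
        return self.strategy.label


def accumulate(
    trace: CohortTrace,
    model: Optional[MarkovModel] = None,
    settings: Optional[EconomicSettings] = None,
) -> EconResult:
    """Sum discounted per-cycle QALYs and costs over a cohort trace.

    Per cycle: occupancy . utility x cycle_length discounted, plus occupancy
    . cycle_cost and entry_flow . one-time entry cost under the same factor.
    """
    settings = settings or EconomicSettings()
    model = model or trace.model
    horizon = trace.horizon
    occ = trace.occupancy[1:]  # rows 1..N: membership after each transition
    entries = trace.entry_flow
    t = np.arange(1, horizon + 1)
    disc = (1.0 + settings.discount_per_cycle) ** (-t)

    qaly_per_cycle = occ @ model.utility * settings.cycle_length
    cost_per_cycle = occ @ model.cycle_cost + entries @ model.entry_cost
    return EconResult(
        strategy=model.strategy,
        total_cost=float(disc @ cost_per_cycle),
        total_qaly=float(disc @ qaly_per_cycle),
        undiscounted_cost=float(cost_per_cycle.sum()),
        undiscounted_qaly=float(qaly_per_cycle.sum()),
    )


def net_monetary_benefit(result: EconResult, wtp: float) -> float:
    """NMB = WTP x QALYs - cost; the CEAC winner maximises this per draw."""
    if wtp < 0:
        raise ParameterError("willingness-to-pay must be >= 0")
    return wtp * result.total_qaly - result.total_cost


STATUS_FRONTIER = "frontier"
STATUS_STRONG = "strongly_dominated"
STATUS_EXTENDED = "extendedly_dominated"


@dataclass(frozen=True)
class FrontierEntry:
    strategy: Strategy
    comparator: Optional[Strategy]  # previous frontier strategy, if any
    delta_cost: Optional[float]
    delta_qaly: Optional[float]
    icer: Optional[float]  # USD/QALY vs comparator; None for cheapest/dominated
    status: str
    total_cost: float = 0.0
    total_qaly: float = 0.0


def icer_frontier(results: Sequence[EconResult]) -> List[FrontierEntry]:
    """Rank strategies by cost and mark the cost-effectiveness frontier.

    Strategies that are costlier and not more effective than some other
    strategy are strongly dominated.  Among the rest (sorted by cost), a
    strategy whose ICER versus the previous surviving strategy exceeds the
    ICER of a later one is extendedly dominated; the process iterates until
    frontier ICERs strictly increase with cost.
    """
    if not results:
        raise ParameterError("need at least one strategy result")
    labels = [r.label for r in results]
    if len(set(labels)) != len(labels):
        raise ParameterError(f"duplicate strategies in frontier input: {sorted(labels)}")

    ordered = sorted(results, key=lambda r: (r.total_cost, r.total_qaly))
    strong = set()
    for r in ordered:
        for other in ordered:
            if other is r:
                continue
            better_or_equal = (
                other.total_cost <= r.total_cost and other.total_qaly >= r.total_qaly
            )
            strictly = (
                other.total_cost < r.total_cost or other.total_qaly > r.total_qaly
            )
            if better_or_equal and strictly:
                strong.add(r.label)
                break

    surviving = [r for r in ordered if r.label not in strong]
    extended = set()
    # iteratively enforce strictly increasing incremental ratios
    while True:
        icers = []
        for prev, cur in zip(surviving, surviving[1:]):
            dq = cur.total_qaly - prev.total_qaly
            dc = cur.total_cost - prev.total_cost
            icers.append(np.inf if dq <= 0 else dc / dq)
        drop = None
        for k in range(len(icers) - 1):
            if icers[k] >= icers[k + 1]:
                drop = surviving[k + 1]
                break
        if drop is None:
            break
        extended.add(drop.label)
        surviving.remove(drop)

    frontier_prev = {
        cur.label: prev for prev, cur in zip(surviving, surviving[1:])
    }
    entries: List[FrontierEntry] = []
    for r in ordered:
        if r.label in strong:
            entries.append(
                FrontierEntry(r.strategy, None, None, None, None, STATUS_STRONG,
                              r.total_cost, r.total_qaly)
            )
        elif r.label in extended:
            entries.append(
                FrontierEntry(r.strategy, None, None, None, None, STATUS_EXTENDED,
                              r.total_cost, r.total_qaly)
            )
        else:
            prev = frontier_prev.get(r.label)
            if prev is None:
                entries.append(
                    FrontierEntry(r.strategy, None, None, None, None,
                                  STATUS_FRONTIER, r.total_cost, r.total_qaly)
                )
            else:
                dc = r.total_cost - prev.total_cost
                dq = r.total_qaly - prev.total_qaly
                entries.append(
                    FrontierEntry(r.strategy, prev.strategy, dc, dq,
                                  dc / dq if dq > 0 else None, STATUS_FRONTIER,
                                  r.total_cost, r.total_qaly)
                )
    return entries


def frontier_table(entries: Iterable[FrontierEntry]) -> pd.DataFrame:
    """Frontier as a summary-table-shaped DataFrame (costs/QALYs/ICER/status)."""
    rows = []
    for e in entries:
        rows.append(
            {
                "strategy": e.strategy.label,
                "induction": e.strategy.induction_drug.value,
                "maintenance": e.strategy.maintenance_drug.value,
                "cumulative_cost_usd": e.total_cost,
                "cumulative_qaly": e.total_qaly,
                "incremental_cost_usd": e.delta_cost,
                "incremental_qaly": e.delta_qaly,
                "icer_usd_per_qaly": e.icer,
                "icer_rounded": None if e.icer is None else round(e.icer),
                "status": e.status,
            }
        )
    return pd.DataFrame(rows)
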