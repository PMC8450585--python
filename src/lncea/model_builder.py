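"""Expand a treatment strategy into an explicit Markov chain.

Pathway encoded here (6-month cycles):

* Primary induction: 2 cycles on the first-line drug; if complete remission
  (CR) is not reached after the first cycle the same drug is extended for a
  second cycle.  Failure after 1 year switches to the other first-line drug
  (2 cycles), then rituximab rescue (2 cycles).  If rituximab also fails the
  patient enters a terminal no-remission state.
* Maintenance: CR on the strategy's maintenance drug; each cycle risks
  relapse, ESRD or death.
* Relapse: one cycle that behaves as re-induction with the initial induction
  drug, followed by a dedicated re-induction tunnel replaying the escalation
  sequence.  Relapse and re-induction carry the elevated ESRD/death risks of
  treatment failure — these patients have already failed to sustain
  remission, and this reading reproduces the published lifetime projections.
* Renal replacement: dialysis first, with a per-cycle chance of living-donor
  transplant; the transplant carries a one-time entry cost.
* Death is absorbing; no age-dependent background mortality is added (the
  only death hazards are the disease-specific ones in the base-case table).

States are tunnel-expanded so stage-duration rules stay expressible in a
memoryless chain; every strategy yields the same 17-state layout.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .parameters import (
    ROW_TOL,
    CostTable,
    EconomicSettings,
    ParameterError,
    ParameterSet,
    TransitionTable,
    UtilityTable,
)


class Drug(str, enum.Enum):
    CYC = "CYC"
    MMF = "MMF"
    AZA = "AZA"
    RTX = "RTX"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class Strategy:
    """One of the six induction->maintenance drug combinations (S1..S6)."""

    label: str
    induction_drug: Drug
    maintenance_drug: Drug

    def __post_init__(self) -> None:
        if self.induction_drug not in (Drug.CYC, Drug.MMF):
            raise ParameterError(
                f"{self.label}: induction drug must be CYC or MMF, "
                f"got {self.induction_drug}"
            )
        if self.maintenance_drug not in (Drug.CYC, Drug.AZA, Drug.MMF):
            raise ParameterError(
                f"{self.label}: maintenance drug must be CYC, AZA or MMF, "
                f"got {self.maintenance_drug}"
            )

    @property
    def second_line_drug(self) -> Drug:
        return Drug.MMF if self.induction_drug is Drug.CYC else Drug.CYC

    def __str__(self) -> str:
        return f"{self.label} ({self.induction_drug}->{self.maintenance_drug})"


#: The six strategies compared in the analysis. S1 (CYC->CYC) is baseline.
STRATEGIES: Dict[str, Strategy] = {
    "S1": Strategy("S1", Drug.CYC, Drug.CYC),
    "S2": Strategy("S2", Drug.MMF, Drug.CYC),
    "S3": Strategy("S3", Drug.CYC, Drug.AZA),
    "S4": Strategy("S4", Drug.MMF, Drug.AZA),
    "S5": Strategy("S5", Drug.CYC, Drug.MMF),
    "S6": Strategy("S6", Drug.MMF, Drug.MMF),
}


@dataclass(frozen=True)
class ExpandedState:
    """One tunnel-expanded Markov state."""

    name: str
    phase: str  # induction | maintenance | renal_replacement | terminal
    drug: Optional[Drug]
    tunnel_index: int = 1
    tags: FrozenSet[str] = frozenset()

    def __post_init__(self) -> None:
        if self.tunnel_index < 1:
            raise ParameterError("tunnel_index must be >= 1")


@dataclass
class MarkovModel:
    """Expanded state list, row-stochastic matrix and per-state payoffs."""

    strategy: Strategy
    states: List[ExpandedState]
    transition: np.ndarray  # (n, n) per-cycle probabilities
    utility: np.ndarray  # (n,)
    cycle_cost: np.ndarray  # (n,) per-cycle cost, USD
    entry_cost: np.ndarray  # (n,) one-time cost charged on entry, USD

    def __post_init__(self) -> None:
        self.index = {s.name: i for i, s in enumerate(self.states)}

    @property
    def n_states(self) -> int:
        return len(self.states)

    def state_index(self, name: str) -> int:
        return self.index[name]

    def tagged(self, tag: str) -> np.ndarray:
        """Boolean mask of states carrying ``tag``."""
        return np.array([tag in s.tags for s in self.states])

    def row(self, name: str) -> Dict[str, float]:
        """Non-zero outgoing probabilities of a state, keyed by destination."""
        i = self.index[name]
        return {
            s.name: float(p)
            for s, p in zip(self.states, self.transition[i])
            if p > 0.0
        }

    def edge_list(self) -> pd.DataFrame:
        """Tabular (from_state, to_state, probability) view for inspection."""
        rows = [
            (a.name, b.name, float(self.transition[i, j]))
            for i, a in enumerate(self.states)
            for j, b in enumerate(self.states)
            if self.transition[i, j] > 0.0
        ]
        return pd.DataFrame(rows, columns=["from_state", "to_state", "probability"])


# state-name helpers ---------------------------------------------------------

DEATH = "Death"
DIALYSIS = "Dialysis"
TRANSPLANT = "Transplant"
FAILURE = "Failure"


def _cr_name(maintenance: Drug) -> str:
    return f"CR-{maintenance}"


def _relapse_name(induction: Drug) -> str:
    return f"Relapse-{induction}"


def build_model(strategy: Strategy, params: ParameterSet) -> MarkovModel:
    """Construct the full Markov model for one strategy.

    Raises :class:`ParameterError` for invalid strategies or any constructed
    row whose probabilities exceed 1.
    """
    if strategy.label not in STRATEGIES:
        raise ParameterError(f"unknown strategy label {strategy.label!r}")
    tt, ut, ct = params.transitions, params.utilities, params.costs
    tt.validate()

    ind, second, maint = (
        strategy.induction_drug,
        strategy.second_line_drug,
        strategy.maintenance_drug,
    )

    # (name, phase, drug, tunnel index, tags)
    primary = [
        (f"Ind-{ind}-1", ind, 1),
        (f"Ind-{ind}-2", ind, 2),
        (f"Ind-{second}-1", second, 1),
        (f"Ind-{second}-2", second, 2),
        ("Ind-RTX-1", Drug.RTX, 1),
        ("Ind-RTX-2", Drug.RTX, 2),
    ]
    re_tunnel = [
        (f"ReInd-{ind}-2", ind, 2),
        (f"ReInd-{second}-1", second, 1),
        (f"ReInd-{second}-2", second, 2),
        ("ReInd-RTX-1", Drug.RTX, 1),
        ("ReInd-RTX-2", Drug.RTX, 2),
    ]

    states: List[ExpandedState] = []
    for name, drug, k in primary:
        states.append(ExpandedState(name, "induction", drug, k))
    for name, drug, k in re_tunnel:
        states.append(ExpandedState(name, "induction", drug, k, frozenset({"re_induction"})))
    states += [
        ExpandedState(FAILURE, "induction", None, 1, frozenset({"treatment_failure"})),
        ExpandedState(_cr_name(maint), "maintenance", maint, 1, frozenset({"in_cr"})),
        ExpandedState(
            _relapse_name(ind), "induction", ind, 1,
            frozenset({"relapse_entry", "re_induction"}),
        ),
        ExpandedState(DIALYSIS, "renal_replacement", None, 1, frozenset({"on_dialysis"})),
        ExpandedState(TRANSPLANT, "renal_replacement", None, 1, frozenset({"post_kt"})),
        ExpandedState(DEATH, "terminal", None, 1, frozenset({"dead"})),
    ]

    idx = {s.name: i for i, s in enumerate(states)}
    n = len(states)
    P = np.zeros((n, n))

    def set_induction_row(name: str, drug: Drug, nxt: str, elevated: bool) -> None:
        cr = tt.induction_cr[drug.value].value
        esrd = (tt.failure_esrd if elevated else tt.induction_esrd).value
        death = (tt.failure_death if elevated else tt.induction_death).value
        stay = 1.0 - cr - esrd - death
        if stay < -ROW_TOL:
            raise ParameterError(
                f"state {name!r}: outgoing probabilities sum to {cr + esrd + death:.4f} > 1"
            )
        i = idx[name]
        P[i, idx[_cr_name(maint)]] = cr
        P[i, idx[DIALYSIS]] = esrd
        P[i, idx[DEATH]] = death
        P[i, idx[nxt]] += max(stay, 0.0)

    # primary induction at base risks
    chain = [name for name, _, _ in primary] + [FAILURE]
    for (name, drug, _), nxt in zip(primary, chain[1:]):
        set_induction_row(name, drug, nxt, elevated=False)
    # relapse re-induction at treatment-failure risks
    rchain = [name for name, _, _ in re_tunnel] + [FAILURE]
    for (name, drug, _), nxt in zip(re_tunnel, rchain[1:]):
        set_induction_row(name, drug, nxt, elevated=True)
    # relapse entry cycle = re-induction cycle 1 on the initial drug
    set_induction_row(_relapse_name(ind), ind, f"ReInd-{ind}-2", elevated=True)

    # terminal no-remission state
    i = idx[FAILURE]
    P[i, idx[DIALYSIS]] = tt.failure_esrd.value
    P[i, idx[DEATH]] = tt.failure_death.value
    P[i, i] = 1.0 - tt.failure_esrd.value - tt.failure_death.value

    # maintenance (complete remission)
    row = tt.maintenance[maint.value]
    i = idx[_cr_name(maint)]
    out = row["relapse"].value + row["esrd"].value + row["death"].value
    if out > 1.0 + ROW_TOL:
        raise ParameterError(
            f"state {_cr_name(maint)!r}: outgoing probabilities sum to {out:.4f} > 1"
        )
    P[i, idx[_relapse_name(ind)]] = row["relapse"].value
    P[i, idx[DIALYSIS]] = row["esrd"].value
    P[i, idx[DEATH]] = row["death"].value
    P[i, i] = 1.0 - out

    # renal replacement
    i = idx[DIALYSIS]
    P[i, idx[TRANSPLANT]] = tt.dialysis_to_kt.value
    P[i, idx[DEATH]] = tt.dialysis_death.value
    P[i, i] = 1.0 - tt.dialysis_to_kt.value - tt.dialysis_death.value
    i = idx[TRANSPLANT]
    P[i, idx[DEATH]] = tt.kt_death.value
    P[i, i] = 1.0 - tt.kt_death.value

    P[idx[DEATH], idx[DEATH]] = 1.0

    # payoffs -----------------------------------------------------------------
    utility = np.zeros(n)
    cycle_cost = np.zeros(n)
    entry_cost = np.zeros(n)
    for s in states:
        i = idx[s.name]
        if "dead" in s.tags:
            utility[i] = ut.death
            cycle_cost[i] = ct.death_cost
        elif "in_cr" in s.tags:
            utility[i] = ut.remission[maint.value].value
            cycle_cost[i] = ct.remission[maint.value].total
        elif "relapse_entry" in s.tags:
            utility[i] = ut.relapse[ind.value].value
            cycle_cost[i] = ct.relapse[ind.value].total
        elif "on_dialysis" in s.tags:
            utility[i] = ut.dialysis.value
            cycle_cost[i] = ct.dialysis.total
        elif "post_kt" in s.tags:
            utility[i] = ut.transplant.value
            cycle_cost[i] = ct.transplant.total
            entry_cost[i] = ct.kt_entry_cost.value
        elif "treatment_failure" in s.tags:
            utility[i] = ut.failure.value
            cycle_cost[i] = ct.failure.total
        else:  # induction tunnel (primary or re-induction)
            utility[i] = ut.induction[s.drug.value].value
            cycle_cost[i] = ct.induction[s.drug.value].total

    model = MarkovModel(strategy, states, P, utility, cycle_cost, entry_cost)
    report = validate_model(model)
    if not report.ok:
        raise ParameterError("constructed model failed validation: " + "; ".join(report.issues))
    return model


@dataclass
class ValidationReport:
    ok: bool
    issues: List[str] = field(default_factory=list)


def validate_model(model: MarkovModel) -> ValidationReport:
    """Structural checks: row-stochastic, absorbing death, death reachable."""
    issues: List[str] = []
    P = model.transition
    sums = P.sum(axis=1)
    for s, total in zip(model.states, sums):
        if abs(total - 1.0) > ROW_TOL:
            issues.append(f"row {s.name!r} sums to {total:.12f}")
    if (P < -ROW_TOL).any():
        issues.append("negative transition probability present")
    d = model.state_index(DEATH)
    if abs(P[d, d] - 1.0) > ROW_TOL or P[d].sum() - P[d, d] > ROW_TOL:
        issues.append("death state is not absorbing")
    # reachability of death from every state (BFS on the support graph)
    n = model.n_states
    reach_death = {d}
    changed = True
    support = P > 0.0
    while changed:
        changed = False
        for i in range(n):
            if i not in reach_death and any(support[i, j] for j in reach_death):
                reach_death.add(i)
                changed = True
    for i, s in enumerate(model.states):
        if i not in reach_death:
            issues.append(f"death unreachable from state {s.name!r}")
    return ValidationReport(ok=not issues, issues=issues)
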