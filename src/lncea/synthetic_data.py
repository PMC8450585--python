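"""Synthetic cost/utility tables and perturbed transition tables.

The published supplementary per-state cost and utility values are not
redistributable, so this module generates stand-in tables that satisfy every
constraint stated in the main analysis text:

* living-state utilities lie in [0.56, 0.94] and death scores 0;
* remission and relapse utilities under cyclophosphamide (CYC) are strictly
  below those under AZA/MMF (adverse-event and infertility burden);
* CYC is the cheapest immunosuppressant, MMF the most expensive
  (CYC < AZA < MMF drug cost ordering);
* the dialysis cycle cost exceeds every drug-state cycle cost;
* kidney transplantation carries a large one-time entry cost, with ongoing
  cycle cost below dialysis (transplant spending is front-loaded);
* every cost decomposes into direct medical, direct non-medical and
  indirect (productivity-loss) components.

Costs are drawn on a log scale between anchors so the orderings hold with
probability one.  Generation is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Tuple

import numpy as np
import yaml

from .parameters import (
    CostComponents,
    CostTable,
    EconomicSettings,
    ParameterError,
    ParameterSet,
    ProbabilityEstimate,
    RangedValue,
    TransitionTable,
    UtilityTable,
)

#: Default seed for the packaged synthetic tables (used by the config fallback).
DEFAULT_SEED = 20190


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic generator.

    ``cost_anchors_usd`` give per-cycle 2019-USD scale anchors
    (log-uniform jitter of +/-10% is applied around each): semi-annual drug
    plus routine-care cost by drug state, the dialysis cycle cost, and the
    one-time transplant entry cost.
    """

    seed: int = DEFAULT_SEED
    utility_low: float = 0.56
    utility_high: float = 0.94
    #: relative half-width of the sensitivity range attached to each cost
    cost_range_frac: float = 0.25
    #: absolute half-width of the sensitivity range attached to each utility
    utility_range: float = 0.05
    #: fraction of the distance to the published bound used when perturbing
    #: transition tables (0 disables perturbation)
    perturbation: float = 0.5
    cost_anchors_usd: Dict[str, float] = field(
        default_factory=lambda: {
            "drug_CYC": 250.0,  # cheapest IS drug, semi-annual
            "drug_AZA": 420.0,
            "drug_MMF": 1600.0,
            "drug_RTX": 4200.0,  # rescue biologic
            "routine_care": 900.0,  # HCQ/GC, tests, visits, admission share
            "adverse_events": 350.0,
            "nonmedical": 180.0,  # transport, accommodation
            "indirect": 420.0,  # daily income x days off work
            "dialysis": 7800.0,  # per-cycle hemodialysis
            "kt_entry": 13000.0,  # one-time living-donor transplant
            "kt_ongoing": 1900.0,  # immunosuppression after transplant
        }
    )

    def __post_init__(self) -> None:
        if not (0.0 <= self.utility_low < self.utility_high <= 1.0):
            raise ParameterError("utility bounds must satisfy 0 <= low < high <= 1")
        if self.perturbation < 0 or self.perturbation > 1:
            raise ParameterError("perturbation must lie in [0, 1]")


def _ranged_u(value: float, cfg: SyntheticConfig) -> RangedValue:
    lo = max(cfg.utility_low, value - cfg.utility_range)
    hi = min(cfg.utility_high, value + cfg.utility_range)
    return RangedValue(value, lo, hi)


def _ranged_c(value: float, cfg: SyntheticConfig) -> RangedValue:
    return RangedValue(value, value * (1 - cfg.cost_range_frac), value * (1 + cfg.cost_range_frac))


def _jitter(rng: np.random.Generator, anchor: float, rel: float = 0.10) -> float:
    """Log-scale jitter that cannot cross an order-of-magnitude anchor gap."""
    return float(anchor * np.exp(rng.uniform(np.log(1 - rel), np.log(1 + rel))))


def generate_cost_utility_tables(
    cfg: SyntheticConfig | None = None,
) -> Tuple[UtilityTable, CostTable]:
    """Build a (UtilityTable, CostTable) pair satisfying all stated constraints."""
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.utility_low, cfg.utility_high
    span = hi - lo

    # utilities: remission best, active disease / failure / dialysis worst;
    # CYC entries strictly lowest within remission and relapse.
    u_rem_aza = lo + span * rng.uniform(0.85, 0.92)
    u_rem_mmf = lo + span * rng.uniform(0.85, 0.92)
    u_rem_cyc = min(u_rem_aza, u_rem_mmf) - span * rng.uniform(0.12, 0.18)
    u_rel_base = lo + span * rng.uniform(0.28, 0.35)
    u_rel = {
        "CYC": u_rel_base - span * rng.uniform(0.08, 0.12),
        "MMF": u_rel_base,
    }
    u_ind = {
        "CYC": lo + span * rng.uniform(0.30, 0.38),
        "MMF": lo + span * rng.uniform(0.34, 0.42),
        "RTX": lo + span * rng.uniform(0.26, 0.34),
    }
    utilities = UtilityTable(
        induction={d: _ranged_u(round(v, 3), cfg) for d, v in u_ind.items()},
        remission={
            "CYC": _ranged_u(round(u_rem_cyc, 3), cfg),
            "AZA": _ranged_u(round(u_rem_aza, 3), cfg),
            "MMF": _ranged_u(round(u_rem_mmf, 3), cfg),
        },
        relapse={d: _ranged_u(round(v, 3), cfg) for d, v in u_rel.items()},
        failure=_ranged_u(round(lo + span * rng.uniform(0.05, 0.12), 3), cfg),
        dialysis=_ranged_u(round(lo + span * rng.uniform(0.02, 0.08), 3), cfg),
        transplant=_ranged_u(round(lo + span * rng.uniform(0.55, 0.65), 3), cfg),
    )
    utilities.validate()

    a = cfg.cost_anchors_usd
    drug = {k: _jitter(rng, a[f"drug_{k}"]) for k in ("CYC", "AZA", "MMF", "RTX")}
    # enforce the drug-cost ordering explicitly (jitter is small, but be safe)
    drug["AZA"] = max(drug["AZA"], drug["CYC"] * 1.2)
    drug["MMF"] = max(drug["MMF"], drug["AZA"] * 1.5)
    care = _jitter(rng, a["routine_care"])
    ae = _jitter(rng, a["adverse_events"])
    nonmed = _jitter(rng, a["nonmedical"])
    indirect = _jitter(rng, a["indirect"])

    def comp(drug_cost: float, dm_extra: float = 0.0, indirect_scale: float = 1.0) -> CostComponents:
        return CostComponents(
            direct_medical=_ranged_c(round(drug_cost + care + ae + dm_extra, 2), cfg),
            direct_nonmedical=_ranged_c(round(nonmed, 2), cfg),
            indirect=_ranged_c(round(indirect * indirect_scale, 2), cfg),
        )

    # induction/relapse cycles are management-heavy; maintenance uses the
    # maintenance drug at roughly half-dose pricing
    induction = {d: comp(drug[d], dm_extra=0.6 * care, indirect_scale=1.5) for d in ("CYC", "MMF", "RTX")}
    remission = {d: comp(0.5 * drug[d], indirect_scale=0.5) for d in ("CYC", "AZA", "MMF")}
    relapse = {d: comp(drug[d], dm_extra=0.8 * care, indirect_scale=1.5) for d in ("CYC", "MMF")}

    dialysis_cost = _jitter(rng, a["dialysis"])
    dialysis_cost = max(
        dialysis_cost,
        1.5 * max(c.total for c in (*induction.values(), *remission.values(), *relapse.values())),
    )
    kt_ongoing = min(_jitter(rng, a["kt_ongoing"]), 0.5 * dialysis_cost)
    kt_entry = max(_jitter(rng, a["kt_entry"]), 1.2 * dialysis_cost)

    costs = CostTable(
        induction=induction,
        remission=remission,
        relapse=relapse,
        failure=comp(0.0, dm_extra=0.5 * care, indirect_scale=1.2),
        dialysis=CostComponents(
            direct_medical=_ranged_c(round(dialysis_cost, 2), cfg),
            direct_nonmedical=_ranged_c(round(2.0 * nonmed, 2), cfg),
            indirect=_ranged_c(round(2.0 * indirect, 2), cfg),
        ),
        transplant=CostComponents(
            direct_medical=_ranged_c(round(kt_ongoing, 2), cfg),
            direct_nonmedical=_ranged_c(round(nonmed, 2), cfg),
            indirect=_ranged_c(round(0.5 * indirect, 2), cfg),
        ),
        kt_entry_cost=_ranged_c(round(kt_entry, 2), cfg),
    )
    costs.validate()
    return utilities, costs


def perturb_transition_table(tt: TransitionTable, cfg: SyntheticConfig | None = None) -> TransitionTable:
    """Jitter every probability within its published sensitivity range.

    Each estimate moves a random fraction (at most ``cfg.perturbation``) of
    the distance toward one of its bounds, so perturbed values always stay
    inside [low, high] and perturbation magnitude 0 returns the table
    unchanged.  The result is validated before being returned.
    """
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    out = tt
    for path, pe in tt.estimates().items():
        if cfg.perturbation == 0 or pe.low == pe.high:
            continue
        u = rng.uniform(-cfg.perturbation, cfg.perturbation)
        if u >= 0:
            value = pe.value + u * (pe.high - pe.value)
        else:
            value = pe.value + u * (pe.value - pe.low)
        out = out.with_value(path, float(np.clip(value, pe.low, pe.high)))
    out.validate()
    return out


def write_config(path: str | Path, params: ParameterSet) -> Path:
    """Serialise a full parameter set to the YAML config format the loader reads."""
    path = Path(path)

    def pe_node(pe: ProbabilityEstimate) -> dict:
        return {
            "estimate": round(pe.value * 100, 6),
            "range": [round(pe.low * 100, 6), round(pe.high * 100, 6)],
            "source": pe.source,
        }

    def rv_node(rv: RangedValue) -> dict:
        return {"value": rv.value, "low": rv.low, "high": rv.high}

    def comp_node(c: CostComponents) -> dict:
        return {
            "direct_medical": rv_node(c.direct_medical),
            "direct_nonmedical": rv_node(c.direct_nonmedical),
            "indirect": rv_node(c.indirect),
        }

    tt, ut, ct, s = params.transitions, params.utilities, params.costs, params.settings
    doc = {
        "transitions": {
            "induction_cr": {d: pe_node(pe) for d, pe in tt.induction_cr.items()},
            "induction_esrd": pe_node(tt.induction_esrd),
            "induction_death": pe_node(tt.induction_death),
            "failure_esrd": pe_node(tt.failure_esrd),
            "failure_death": pe_node(tt.failure_death),
            "maintenance": {
                d: {k: pe_node(pe) for k, pe in row.items()} for d, row in tt.maintenance.items()
            },
            "dialysis_to_kt": pe_node(tt.dialysis_to_kt),
            "dialysis_death": pe_node(tt.dialysis_death),
            "kt_death": pe_node(tt.kt_death),
        },
        "utilities": {
            "induction": {d: rv_node(rv) for d, rv in ut.induction.items()},
            "remission": {d: rv_node(rv) for d, rv in ut.remission.items()},
            "relapse": {d: rv_node(rv) for d, rv in ut.relapse.items()},
            "failure": rv_node(ut.failure),
            "dialysis": rv_node(ut.dialysis),
            "transplant": rv_node(ut.transplant),
        },
        "costs": {
            "induction": {d: comp_node(c) for d, c in ct.induction.items()},
            "remission": {d: comp_node(c) for d, c in ct.remission.items()},
            "relapse": {d: comp_node(c) for d, c in ct.relapse.items()},
            "failure": comp_node(ct.failure),
            "dialysis": comp_node(ct.dialysis),
            "transplant": comp_node(ct.transplant),
            "kt_entry_cost": rv_node(ct.kt_entry_cost),
        },
        "economics": {
            "cycle_length": s.cycle_length,
            "discount_per_cycle": s.discount_per_cycle,
            "discount_low": s.discount_low,
            "discount_high": s.discount_high,
            "horizon_cycles": s.horizon_cycles,
            "cohort_size": s.cohort_size,
            "wtp_1x": s.wtp_1x,
            "wtp_3x": s.wtp_3x,
            "cny_per_usd": s.cny_per_usd,
            "psa_draws": s.psa_draws,
        },
    }
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path
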