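"""Deterministic (tornado) and probabilistic sensitivity analysis.

One-way DSA moves each parameter to its low and high bound, rebuilds the
models, and records the ICER of a target strategy pair at both ends.

PSA re-samples every parameter from its assigned family — Dirichlet for
transition probabilities (per source-state simplex, pseudo-counts matched to
the base-case means), truncated normal for utilities, gamma for costs
(moment-matched to the base value and range-implied SD), and an equal-
probability two-point ("binomial") distribution for the discount rate —
then reruns all six strategies per draw.  Cost-effectiveness acceptability
curves report, at each willingness-to-pay value, the fraction of draws in
which each strategy has the highest net monetary benefit (ties split).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_engine import simulate
from .economics import EconResult, accumulate, net_monetary_benefit
from .model_builder import STRATEGIES, MarkovModel, Strategy, build_model
from .parameters import (
    EconomicSettings,
    ParameterError,
    ParameterSet,
    ProbabilityEstimate,
)

logger = logging.getLogger("lncea")

#: Effective sample size for Dirichlet pseudo-counts; chosen so marginal SDs
#: roughly span the published sensitivity ranges.
DEFAULT_DIRICHLET_ESS = 100.0


# ---------------------------------------------------------------------------
# parameter registry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParameterRef:
    """One scalar input: its dotted path, base value, bounds and setter."""

    name: str
    base: float
    low: float
    high: float
    kind: str  # transition | utility | cost | discount

    def apply(self, params: ParameterSet, value: float) -> ParameterSet:
        if self.kind == "transition":
            return replace(params, transitions=params.transitions.with_value(self.name, value))
        if self.kind == "utility":
            return replace(params, utilities=params.utilities.with_value(self.name, value))
        if self.kind == "cost":
            return replace(params, costs=params.costs.with_value(self.name, value))
        if self.kind == "discount":
            return replace(
                params, settings=replace(params.settings, discount_per_cycle=value)
            )
        raise ParameterError(f"unknown parameter kind {self.kind!r}")


def enumerate_parameters(params: ParameterSet) -> List[ParameterRef]:
    """Every tunable scalar with bounds: transitions, utilities, costs, discount."""
    refs: List[ParameterRef] = []
    for name, pe in params.transitions.estimates().items():
        refs.append(ParameterRef(name, pe.value, pe.low, pe.high, "transition"))
    for name, rv in params.utilities.items().items():
        refs.append(ParameterRef(f"utilities.{name}", rv.value, rv.low, rv.high, "utility"))
    for name, rv in params.costs.scalars().items():
        refs.append(ParameterRef(name, rv.value, rv.low, rv.high, "cost"))
    s = params.settings
    refs.append(
        ParameterRef(
            "economics.discount_per_cycle",
            s.discount_per_cycle,
            s.discount_low,
            s.discount_high,
            "discount",
        )
    )
    return refs


# ---------------------------------------------------------------------------
# deterministic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DSAResult:
    parameter: str
    icer_at_low: float
    icer_at_high: float
    base_icer: float

    @property
    def spread(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


def _pair_icer(params: ParameterSet, target: Strategy, comparator: Strategy) -> float:
    """ICER of target vs comparator at the configured horizon."""
    econ = {}
    for strat in (comparator, target):
        model = build_model(strat, params)
        trace = simulate(model, params.settings)
        econ[strat.label] = accumulate(trace, model, params.settings)
    dq = econ[target.label].total_qaly - econ[comparator.label].total_qaly
    dc = econ[target.label].total_cost - econ[comparator.label].total_cost
    if dq == 0:
        return float("inf")
    return dc / dq


def one_way_dsa(
    params: ParameterSet,
    target: Strategy = STRATEGIES["S3"],
    comparator: Strategy = STRATEGIES["S1"],
    parameters: Optional[Sequence[ParameterRef]] = None,
) -> List[DSAResult]:
    """Tornado analysis: vary each parameter alone over its bounds.

    Parameters without a proper range (low == high == base) yield zero
    spread; parameters that cannot produce a valid model at a bound are
    skipped with a warning.  Results are sorted by spread, descending.
    """
    refs = list(parameters) if parameters is not None else enumerate_parameters(params)
    base_icer = _pair_icer(params, target, comparator)
    results: List[DSAResult] = []
    for ref in refs:
        try:
            lo = _pair_icer(ref.apply(params, ref.low), target, comparator)
            hi = _pair_icer(ref.apply(params, ref.high), target, comparator)
        except ParameterError as exc:
            logger.warning("DSA skipping %s: %s", ref.name, exc)
            continue
        results.append(DSAResult(ref.name, lo, hi, base_icer))
    results.sort(key=lambda r: r.spread, reverse=True)
    return results


def tornado_table(results: Sequence[DSAResult], top: Optional[int] = 12) -> pd.DataFrame:
    """Tornado-plot data (top-N by spread; pass ``top=None`` for the full table)."""
    rows = [
        {
            "parameter": r.parameter,
            "icer_at_low": r.icer_at_low,
            "icer_at_high": r.icer_at_high,
            "base_icer": r.base_icer,
            "spread": r.spread,
        }
        for r in (results if top is None else results[:top])
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# distributions for PSA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DistributionSpec:
    """Sampling recipe for one parameter (or one simplex group of them)."""

    family: str  # dirichlet | normal | gamma | binomial | point
    names: Tuple[str, ...]  # parameter paths drawn jointly (len > 1 only for dirichlet)
    params: Dict[str, object]

    def sample(self, rng: np.random.Generator) -> Dict[str, float]:
        if self.family == "point":
            return {self.names[0]: float(self.params["value"])}
        if self.family == "dirichlet":
            alpha = np.asarray(self.params["alpha"], dtype=float)
            draw = rng.dirichlet(alpha)
            # last component is the residual stay probability, not assigned
            return {n: float(v) for n, v in zip(self.names, draw[: len(self.names)])}
        if self.family == "normal":
            mu, sd = float(self.params["mu"]), float(self.params["sd"])
            lo, hi = self.params.get("bounds", (0.0, 1.0))
            a, b = (lo - mu) / sd, (hi - mu) / sd
            return {self.names[0]: float(stats.truncnorm.rvs(a, b, loc=mu, scale=sd, random_state=rng))}
        if self.family == "gamma":
            shape, scale = float(self.params["shape"]), float(self.params["scale"])
            return {self.names[0]: float(rng.gamma(shape, scale))}
        if self.family == "binomial":
            lo, hi = float(self.params["low"]), float(self.params["high"])
            return {self.names[0]: float(lo if rng.random() < 0.5 else hi)}
        raise ParameterError(f"unknown distribution family {self.family!r}")


def _dirichlet_group(
    names: Sequence[str], probs: Sequence[float], ess: float
) -> DistributionSpec:
    residual = 1.0 - sum(probs)
    alpha = [max(p * ess, 1e-6) for p in probs] + [max(residual * ess, 1e-6)]
    return DistributionSpec("dirichlet", tuple(names), {"alpha": alpha})


def build_distributions(
    params: ParameterSet, ess: float = DEFAULT_DIRICHLET_ESS
) -> List[DistributionSpec]:
    """Assign a sampling distribution to every tunable parameter.

    Transition probabilities are grouped by source state and drawn from a
    Dirichlet whose pseudo-counts are ``ess`` times the base probabilities
    (the residual "stay" mass takes the remaining concentration).  Utilities
    use a [0, 1]-truncated normal and costs a gamma, both with SD implied by
    the sensitivity range, ``sd = (high - low) / (2 x 1.96)``.  The discount
    rate flips between its two bounds.  Degenerate ranges collapse to point
    masses.
    """
    tt = params.transitions
    specs: List[DistributionSpec] = []

    # transition simplex groups (each group shares a source state)
    for drug, pe in tt.induction_cr.items():
        specs.append(_dirichlet_group([f"transitions.induction_cr.{drug}"], [pe.value], ess))
    specs.append(
        _dirichlet_group(
            ["transitions.induction_esrd", "transitions.induction_death"],
            [tt.induction_esrd.value, tt.induction_death.value],
            ess,
        )
    )
    specs.append(
        _dirichlet_group(
            ["transitions.failure_esrd", "transitions.failure_death"],
            [tt.failure_esrd.value, tt.failure_death.value],
            ess,
        )
    )
    for drug, row in tt.maintenance.items():
        specs.append(
            _dirichlet_group(
                [f"transitions.maintenance.{drug}.{k}" for k in ("relapse", "esrd", "death")],
                [row[k].value for k in ("relapse", "esrd", "death")],
                ess,
            )
        )
    specs.append(
        _dirichlet_group(
            ["transitions.dialysis_to_kt", "transitions.dialysis_death"],
            [tt.dialysis_to_kt.value, tt.dialysis_death.value],
            ess,
        )
    )
    specs.append(_dirichlet_group(["transitions.kt_death"], [tt.kt_death.value], ess))

    for name, rv in params.utilities.items().items():
        sd = (rv.high - rv.low) / (2 * 1.96)
        if sd <= 0:
            specs.append(DistributionSpec("point", (f"utilities.{name}",), {"value": rv.value}))
        else:
            specs.append(
                DistributionSpec(
                    "normal",
                    (f"utilities.{name}",),
                    {"mu": rv.value, "sd": sd, "bounds": (0.0, 1.0)},
                )
            )

    for name, rv in params.costs.scalars().items():
        sd = (rv.high - rv.low) / (2 * 1.96)
        if sd <= 0 or rv.value <= 0:
            specs.append(DistributionSpec("point", (name,), {"value": rv.value}))
        else:
            shape = (rv.value / sd) ** 2
            scale = sd**2 / rv.value
            specs.append(DistributionSpec("gamma", (name,), {"shape": shape, "scale": scale}))

    s = params.settings
    if s.discount_low == s.discount_high:
        specs.append(
            DistributionSpec("point", ("economics.discount_per_cycle",), {"value": s.discount_per_cycle})
        )
    else:
        specs.append(
            DistributionSpec(
                "binomial",
                ("economics.discount_per_cycle",),
                {"low": s.discount_low, "high": s.discount_high},
            )
        )
    return specs


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PSASample:
    """Cost/QALY of every strategy in one sampled parameter world."""

    draw: int
    values: Mapping[str, float]  # sampled parameter values by path
    results: Mapping[str, EconResult]  # keyed by strategy label


def _apply_values(params: ParameterSet, values: Mapping[str, float]) -> ParameterSet:
    out = params
    refs = {r.name: r for r in enumerate_parameters(params)}
    for name, value in values.items():
        out = refs[name].apply(out, value)
    return out


def run_psa(
    params: ParameterSet,
    n_draws: Optional[int] = None,
    seed: int = 0,
    strategies: Optional[Sequence[Strategy]] = None,
    distributions: Optional[Sequence[DistributionSpec]] = None,
    max_resample: int = 100,
) -> List[PSASample]:
    """Sample parameter worlds and rerun every strategy in each.

    Sampled tables that violate validity (a source row summing above 1) are
    resampled, with the total resample count logged.  Fully reproducible
    from the seed.
    """
    n_draws = int(n_draws if n_draws is not None else params.settings.psa_draws)
    if n_draws < 1:
        raise ParameterError("n_draws must be >= 1")
    strategies = list(strategies) if strategies is not None else list(STRATEGIES.values())
    dists = list(distributions) if distributions is not None else build_distributions(params)
    rng = np.random.default_rng(seed)

    samples: List[PSASample] = []
    resamples = 0
    for draw in range(n_draws):
        for attempt in range(max_resample):
            values: Dict[str, float] = {}
            for spec in dists:
                values.update(spec.sample(rng))
            try:
                world = _apply_values(params, values)
                # sampling-level validity: transition rows must stay simplex;
                # base-case-only style constraints (utility band/orderings)
                # do not bind sampled worlds
                world.transitions.validate()
                break
            except ParameterError:
                resamples += 1
        else:
            raise ParameterError(
                f"draw {draw}: no valid parameter world in {max_resample} attempts"
            )
        results: Dict[str, EconResult] = {}
        for strat in strategies:
            model = build_model(strat, world)
            trace = simulate(model, world.settings)
            results[strat.label] = accumulate(trace, model, world.settings)
        samples.append(PSASample(draw, values, results))
    if resamples:
        logger.info("PSA resampled %d invalid parameter worlds", resamples)
    return samples


@dataclass(frozen=True)
class CEACPoint:
    wtp: float
    acceptability: Mapping[str, float]  # strategy label -> probability


def ceac(samples: Sequence[PSASample], wtp_grid: Sequence[float]) -> List[CEACPoint]:
    """Cost-effectiveness acceptability: P(highest NMB) per strategy per WTP."""
    if not samples:
        raise ParameterError("need at least one PSA sample")
    wtps = list(wtp_grid)
    if not wtps:
        raise ParameterError("WTP grid must not be empty")
    labels = sorted(samples[0].results)
    qalys = np.array([[s.results[l].total_qaly for l in labels] for s in samples])
    costs = np.array([[s.results[l].total_cost for l in labels] for s in samples])
    points: List[CEACPoint] = []
    for wtp in wtps:
        nmb = wtp * qalys - costs
        best = nmb.max(axis=1, keepdims=True)
        winners = np.isclose(nmb, best, rtol=0.0, atol=1e-9)
        share = winners / winners.sum(axis=1, keepdims=True)  # ties split equally
        accept = share.mean(axis=0)
        points.append(CEACPoint(float(wtp), dict(zip(labels, map(float, accept)))))
    return points


def default_wtp_grid(settings: EconomicSettings, step: float = 500.0, top: float = 50_000.0) -> List[float]:
    """0..top in ``step`` increments, guaranteed to include both GDP thresholds."""
    grid = set(np.arange(0.0, top + step / 2, step).tolist())
    grid.update((settings.wtp_1x, settings.wtp_3x))
    return sorted(grid)


def ceac_table(points: Sequence[CEACPoint]) -> pd.DataFrame:
    rows = [
        {"wtp": p.wtp, "strategy": label, "acceptability": prob}
        for p in points
        for label, prob in sorted(p.acceptability.items())
    ]
    return pd.DataFrame(rows)


def ce_plane_table(samples: Sequence[PSASample], comparator: str = "S1") -> pd.DataFrame:
    """CE-plane points: per-draw incremental cost/QALY vs the comparator."""
    rows = []
    for s in samples:
        base = s.results[comparator]
        for label, res in sorted(s.results.items()):
            if label == comparator:
                continue
            rows.append(
                {
                    "draw": s.draw,
                    "strategy": label,
                    "delta_cost": res.total_cost - base.total_cost,
                    "delta_qaly": res.total_qaly - base.total_qaly,
                }
            )
    return pd.DataFrame(rows)
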