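"""Model inputs: transition probabilities, utilities, costs, and economic settings.

All probabilities are stored internally as proportions per 6-month cycle
(e.g. 0.4084).  The plain-text config format carries transition estimates as
*percentages*, exactly as clinical tables print them, and the loader divides
by 100 once — this keeps the packaged defaults diffable against the published
table and removes transcription ambiguity.

Costs are expressed in 2019 USD.  The only currency operation implemented is
the single CNY→USD conversion at the 2019 exchange rate (1 USD = 6.87 CNY);
inflation adjustment is out of scope.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Dict, Mapping, Optional, Tuple

import yaml

try:  # Python >= 3.9
    from importlib import resources as _resources
except ImportError:  # pragma: no cover
    import importlib_resources as _resources  # type: ignore

logger = logging.getLogger("lncea")

INDUCTION_DRUGS = ("CYC", "MMF", "RTX")
FIRST_LINE_DRUGS = ("CYC", "MMF")
MAINTENANCE_DRUGS = ("CYC", "AZA", "MMF")

#: Row-stochasticity / simplex tolerance used across the package.
ROW_TOL = 1e-10


class ParameterError(ValueError):
    """A parameter value or table violates its validity constraints."""


# ---------------------------------------------------------------------------
# probability estimates and the transition table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProbabilityEstimate:
    """A per-cycle transition probability with its sensitivity range.

    ``low`` and ``high`` bound the one-way sensitivity interval (taken from
    systematic-review ranges or 95% CIs in the source literature).
    """

    value: float
    low: float
    high: float
    source: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.low <= self.value <= self.high <= 1.0):
            raise ParameterError(
                f"probability estimate out of order or range: "
                f"low={self.low}, value={self.value}, high={self.high} "
                f"(source={self.source!r})"
            )


@dataclass(frozen=True)
class TransitionTable:
    """Base-case 6-month transition probabilities for the whole pathway.

    ``induction_cr`` maps induction drug (CYC/MMF/RTX) to the per-cycle
    probability of reaching complete remission.  ``induction_esrd`` and
    ``induction_death`` apply to every primary induction cycle regardless of
    drug.  ``failure_esrd``/``failure_death`` are the elevated risks for
    patients without complete remission after immunosuppressive treatment;
    they govern the terminal no-remission state and relapse re-induction.
    ``maintenance`` maps maintenance drug to ``{"relapse", "esrd", "death"}``.
    """

    induction_cr: Mapping[str, ProbabilityEstimate]
    induction_esrd: ProbabilityEstimate
    induction_death: ProbabilityEstimate
    failure_esrd: ProbabilityEstimate
    failure_death: ProbabilityEstimate
    maintenance: Mapping[str, Mapping[str, ProbabilityEstimate]]
    dialysis_to_kt: ProbabilityEstimate
    dialysis_death: ProbabilityEstimate
    kt_death: ProbabilityEstimate

    def validate(self) -> None:
        """Check every source state's outgoing probabilities sum to <= 1."""
        for drug in INDUCTION_DRUGS:
            if drug not in self.induction_cr:
                raise ParameterError(f"transitions.induction_cr missing drug {drug}")
        rows = {}
        for drug, pe in self.induction_cr.items():
            rows[f"induction[{drug}]"] = (
                pe.value + self.induction_esrd.value + self.induction_death.value
            )
            rows[f"re_induction[{drug}]"] = (
                pe.value + self.failure_esrd.value + self.failure_death.value
            )
        rows["treatment_failure"] = self.failure_esrd.value + self.failure_death.value
        for drug in MAINTENANCE_DRUGS:
            if drug not in self.maintenance:
                raise ParameterError(f"transitions.maintenance missing drug {drug}")
            row = self.maintenance[drug]
            for key in ("relapse", "esrd", "death"):
                if key not in row:
                    raise ParameterError(
                        f"transitions.maintenance.{drug} missing key {key!r}"
                    )
            rows[f"maintenance[{drug}]"] = sum(p.value for p in row.values())
        rows["dialysis"] = self.dialysis_to_kt.value + self.dialysis_death.value
        rows["transplant"] = self.kt_death.value
        for name, total in rows.items():
            if total > 1.0 + ROW_TOL:
                raise ParameterError(
                    f"outgoing probabilities for state {name!r} sum to {total:.4f} > 1"
                )

    def estimates(self) -> Dict[str, ProbabilityEstimate]:
        """Flat view of every estimate, keyed by dotted parameter path."""
        out: Dict[str, ProbabilityEstimate] = {}
        for drug, pe in self.induction_cr.items():
            out[f"transitions.induction_cr.{drug}"] = pe
        out["transitions.induction_esrd"] = self.induction_esrd
        out["transitions.induction_death"] = self.induction_death
        out["transitions.failure_esrd"] = self.failure_esrd
        out["transitions.failure_death"] = self.failure_death
        for drug, row in self.maintenance.items():
            for key, pe in row.items():
                out[f"transitions.maintenance.{drug}.{key}"] = pe
        out["transitions.dialysis_to_kt"] = self.dialysis_to_kt
        out["transitions.dialysis_death"] = self.dialysis_death
        out["transitions.kt_death"] = self.kt_death
        return out

    def with_value(self, path: str, value: float) -> "TransitionTable":
        """Return a copy with the estimate at ``path`` set to ``value``.

        Bounds are widened to admit the new value so that sensitivity
        analyses can push a parameter to the edge of its own range.
        """
        parts = path.split(".")
        if parts[0] == "transitions":
            parts = parts[1:]

        def upd(pe: ProbabilityEstimate) -> ProbabilityEstimate:
            return ProbabilityEstimate(
                value=value,
                low=min(pe.low, value),
                high=max(pe.high, value),
                source=pe.source,
            )

        if parts[0] == "induction_cr":
            m = dict(self.induction_cr)
            m[parts[1]] = upd(m[parts[1]])
            return replace(self, induction_cr=m)
        if parts[0] == "maintenance":
            m = {d: dict(row) for d, row in self.maintenance.items()}
            m[parts[1]][parts[2]] = upd(m[parts[1]][parts[2]])
            return replace(self, maintenance=m)
        if parts[0] in (
            "induction_esrd",
            "induction_death",
            "failure_esrd",
            "failure_death",
            "dialysis_to_kt",
            "dialysis_death",
            "kt_death",
        ):
            return replace(self, **{parts[0]: upd(getattr(self, parts[0]))})
        raise KeyError(f"unknown transition parameter path: {path}")


# ---------------------------------------------------------------------------
# utilities and costs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RangedValue:
    """A scalar input with one-way sensitivity bounds (low <= value <= high)."""

    value: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (self.low <= self.value <= self.high):
            raise ParameterError(
                f"ranged value out of order: low={self.low}, value={self.value}, "
                f"high={self.high}"
            )


@dataclass(frozen=True)
class UtilityTable:
    """Per-state EQ-5D utility scores (dimensionless, 0 = death, 1 = full health).

    Living-state utilities lie in [0.56, 0.94].  Remission and relapse
    utilities are keyed by drug; the CYC entries are strictly the lowest,
    reflecting adverse-event and infertility burden of cyclophosphamide.
    """

    induction: Mapping[str, RangedValue]  # keyed by induction drug incl. RTX
    remission: Mapping[str, RangedValue]  # keyed by maintenance drug
    relapse: Mapping[str, RangedValue]  # keyed by re-induction (first-line) drug
    failure: RangedValue
    dialysis: RangedValue
    transplant: RangedValue
    death: float = 0.0

    LIVING_LOW = 0.56
    LIVING_HIGH = 0.94

    def validate(self) -> None:
        if self.death != 0.0:
            raise ParameterError("utilities.death must be exactly 0")
        for name, rv in self.items().items():
            if not (self.LIVING_LOW <= rv.value <= self.LIVING_HIGH):
                raise ParameterError(
                    f"utilities.{name} = {rv.value} outside [{self.LIVING_LOW}, "
                    f"{self.LIVING_HIGH}]"
                )
        others = [self.remission[d].value for d in ("AZA", "MMF") if d in self.remission]
        if others and self.remission["CYC"].value >= min(others):
            raise ParameterError(
                "utilities.remission.CYC must be strictly below AZA and MMF remission"
            )

    def items(self) -> Dict[str, RangedValue]:
        out: Dict[str, RangedValue] = {}
        for drug, rv in self.induction.items():
            out[f"induction.{drug}"] = rv
        for drug, rv in self.remission.items():
            out[f"remission.{drug}"] = rv
        for drug, rv in self.relapse.items():
            out[f"relapse.{drug}"] = rv
        out["failure"] = self.failure
        out["dialysis"] = self.dialysis
        out["transplant"] = self.transplant
        return out

    def with_value(self, path: str, value: float) -> "UtilityTable":
        parts = path.split(".")
        if parts[0] == "utilities":
            parts = parts[1:]
        rv = RangedValue(value, min(value, 0.0), max(value, 1.0))
        if parts[0] in ("induction", "remission", "relapse"):
            m = dict(getattr(self, parts[0]))
            m[parts[1]] = rv
            return replace(self, **{parts[0]: m})
        if parts[0] in ("failure", "dialysis", "transplant"):
            return replace(self, **{parts[0]: rv})
        raise KeyError(f"unknown utility parameter path: {path}")


@dataclass(frozen=True)
class CostComponents:
    """Per-cycle cost of one health state, decomposed by payer perspective.

    direct_medical: drugs, adverse-event management, tests, admission.
    direct_nonmedical: transport, accommodation, social services.
    indirect: productivity loss (daily income x days off work).
    Each component carries its own sensitivity bounds.
    """

    direct_medical: RangedValue
    direct_nonmedical: RangedValue
    indirect: RangedValue

    @property
    def total(self) -> float:
        return (
            self.direct_medical.value
            + self.direct_nonmedical.value
            + self.indirect.value
        )

    def validate(self, name: str) -> None:
        for f in fields(self):
            rv = getattr(self, f.name)
            if rv.low < 0 or rv.value < 0:
                raise ParameterError(f"costs.{name}.{f.name} must be >= 0")


@dataclass(frozen=True)
class CostTable:
    """Per-state per-cycle costs (2019 USD) plus the one-time transplant cost.

    ``kt_entry_cost`` is charged once on entry into the transplant state
    (living-donor surgery and perioperative care); the ongoing transplant
    cycle cost is below the dialysis cycle cost, reflecting that transplant
    spending is front-loaded.
    """

    induction: Mapping[str, CostComponents]
    remission: Mapping[str, CostComponents]
    relapse: Mapping[str, CostComponents]
    failure: CostComponents
    dialysis: CostComponents
    transplant: CostComponents
    kt_entry_cost: RangedValue
    death_cost: float = 0.0

    def validate(self) -> None:
        for name, comp in self.items().items():
            comp.validate(name)
        if self.kt_entry_cost.value < 0:
            raise ParameterError("costs.kt_entry_cost must be >= 0")
        if self.transplant.total >= self.dialysis.total:
            raise ParameterError(
                "ongoing transplant cycle cost must be below dialysis cycle cost"
            )

    def items(self) -> Dict[str, CostComponents]:
        out: Dict[str, CostComponents] = {}
        for drug, c in self.induction.items():
            out[f"induction.{drug}"] = c
        for drug, c in self.remission.items():
            out[f"remission.{drug}"] = c
        for drug, c in self.relapse.items():
            out[f"relapse.{drug}"] = c
        out["failure"] = self.failure
        out["dialysis"] = self.dialysis
        out["transplant"] = self.transplant
        return out

    def scalars(self) -> Dict[str, RangedValue]:
        """Flat view of every cost scalar keyed by dotted path."""
        out: Dict[str, RangedValue] = {}
        for name, comp in self.items().items():
            for f in fields(comp):
                out[f"costs.{name}.{f.name}"] = getattr(comp, f.name)
        out["costs.kt_entry_cost"] = self.kt_entry_cost
        return out

    def with_value(self, path: str, value: float) -> "CostTable":
        parts = path.split(".")
        if parts[0] == "costs":
            parts = parts[1:]
        rv = RangedValue(value, min(value, 0.0), value)
        if parts[0] == "kt_entry_cost":
            return replace(self, kt_entry_cost=rv)
        group, comp_name = parts[0], parts[-1]
        if group in ("induction", "remission", "relapse"):
            m = dict(getattr(self, group))
            m[parts[1]] = replace(m[parts[1]], **{comp_name: rv})
            return replace(self, **{group: m})
        if group in ("failure", "dialysis", "transplant"):
            comp = replace(getattr(self, group), **{comp_name: rv})
            return replace(self, **{group: comp})
        raise KeyError(f"unknown cost parameter path: {path}")


# ---------------------------------------------------------------------------
# economic settings
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EconomicSettings:
    """Run-level economic constants.

    The discount rate is 1.5% per 6-month cycle (3% per year).  Willingness
    to pay is anchored at one and three times 2019 Chinese GDP per capita.
    ``discount_low``/``discount_high`` bound the discount rate for
    sensitivity analysis (the base-case range spans 0–3% per cycle).
    """

    cycle_length: float = 0.5  # years
    discount_per_cycle: float = 0.015
    discount_low: float = 0.0
    discount_high: float = 0.03
    horizon_cycles: int = 60  # 60 = lifetime (30 y); 6 = 3-year horizon
    cohort_size: int = 1000
    wtp_1x: float = 10_319.0  # USD/QALY, 1x GDP per capita (2019)
    wtp_3x: float = 30_957.0  # USD/QALY, 3x GDP per capita (2019)
    cny_per_usd: float = 6.87
    psa_draws: int = 1000

    def __post_init__(self) -> None:
        if self.horizon_cycles < 1:
            raise ParameterError("horizon_cycles must be >= 1")
        if self.discount_per_cycle < 0:
            raise ParameterError("discount_per_cycle must be >= 0")
        if not self.wtp_1x < self.wtp_3x:
            raise ParameterError("wtp_1x must be below wtp_3x")
        if self.cycle_length <= 0:
            raise ParameterError("cycle_length must be positive")


@dataclass(frozen=True)
class ParameterSet:
    """Bundle of all model inputs for one analysis."""

    transitions: TransitionTable
    utilities: UtilityTable
    costs: CostTable
    settings: EconomicSettings

    def validate(self) -> "ParameterSet":
        self.transitions.validate()
        self.utilities.validate()
        self.costs.validate()
        return self


# ---------------------------------------------------------------------------
# probability and currency conversions
# ---------------------------------------------------------------------------


def annual_to_cycle_prob(p_annual: float, cycle_years: float) -> float:
    """Rescale an annual transition probability to a shorter/longer cycle.

    Assumes a constant hazard within the year, so the per-cycle probability
    is ``1 - (1 - p)^t`` with ``t`` in years.
    """
    if not (0.0 <= p_annual <= 1.0):
        raise ParameterError(f"annual probability {p_annual} outside [0, 1]")
    if cycle_years <= 0:
        raise ParameterError("cycle_years must be positive")
    return 1.0 - (1.0 - p_annual) ** cycle_years


def cycle_to_annual_prob(p_cycle: float, cycle_years: float) -> float:
    """Inverse of :func:`annual_to_cycle_prob` (round-trip identity holds)."""
    if not (0.0 <= p_cycle <= 1.0):
        raise ParameterError(f"cycle probability {p_cycle} outside [0, 1]")
    if cycle_years <= 0:
        raise ParameterError("cycle_years must be positive")
    if p_cycle == 1.0:
        return 1.0
    return 1.0 - math.exp(math.log1p(-p_cycle) / cycle_years)


def convert_cny_to_usd(amount_cny: float, settings: Optional[EconomicSettings] = None) -> float:
    """Convert 2019 CNY to 2019 USD at the fixed study exchange rate."""
    if amount_cny < 0:
        raise ParameterError("cannot convert a negative amount")
    rate = (settings or EconomicSettings()).cny_per_usd
    return amount_cny / rate


# ---------------------------------------------------------------------------
# config file I/O
# ---------------------------------------------------------------------------

_DEFAULTS_RESOURCE = "defaults.yaml"


def default_config_path() -> Path:
    """Path of the packaged base-case parameter file."""
    return Path(str(_resources.files("lncea").joinpath("data", _DEFAULTS_RESOURCE)))


def _parse_pct(node, key: str) -> ProbabilityEstimate:
    """Parse ``{estimate: 40.84, range: [21.74, 66.67], source: ...}`` percents."""
    try:
        value = float(node["estimate"]) / 100.0
        low, high = (float(x) / 100.0 for x in node.get("range", [node["estimate"]] * 2))
    except (KeyError, TypeError, ValueError) as exc:
        raise ParameterError(f"malformed transition entry at {key!r}: {exc}") from exc
    try:
        return ProbabilityEstimate(value, low, high, source=str(node.get("source", "")))
    except ParameterError as exc:
        raise ParameterError(f"invalid probability at {key!r}: {exc}") from exc


def _parse_transitions(doc: Mapping) -> TransitionTable:
    t = doc["transitions"]
    ind_cr = {
        d: _parse_pct(t["induction_cr"][d], f"transitions.induction_cr.{d}")
        for d in INDUCTION_DRUGS
    }
    maint = {
        d: {
            k: _parse_pct(
                t["maintenance"][d][k], f"transitions.maintenance.{d}.{k}"
            )
            for k in ("relapse", "esrd", "death")
        }
        for d in MAINTENANCE_DRUGS
    }
    return TransitionTable(
        induction_cr=ind_cr,
        induction_esrd=_parse_pct(t["induction_esrd"], "transitions.induction_esrd"),
        induction_death=_parse_pct(t["induction_death"], "transitions.induction_death"),
        failure_esrd=_parse_pct(t["failure_esrd"], "transitions.failure_esrd"),
        failure_death=_parse_pct(t["failure_death"], "transitions.failure_death"),
        maintenance=maint,
        dialysis_to_kt=_parse_pct(t["dialysis_to_kt"], "transitions.dialysis_to_kt"),
        dialysis_death=_parse_pct(t["dialysis_death"], "transitions.dialysis_death"),
        kt_death=_parse_pct(t["kt_death"], "transitions.kt_death"),
    )


def _parse_ranged(node, key: str) -> RangedValue:
    try:
        if isinstance(node, Mapping):
            value = float(node["value"])
            low = float(node.get("low", value))
            high = float(node.get("high", value))
        else:
            value = float(node)
            low = high = value
    except (KeyError, TypeError, ValueError) as exc:
        raise ParameterError(f"malformed value at {key!r}: {exc}") from exc
    try:
        return RangedValue(value, low, high)
    except ParameterError as exc:
        raise ParameterError(f"invalid range at {key!r}: {exc}") from exc


def _parse_utilities(doc: Mapping) -> UtilityTable:
    u = doc["utilities"]
    return UtilityTable(
        induction={d: _parse_ranged(u["induction"][d], f"utilities.induction.{d}") for d in u["induction"]},
        remission={d: _parse_ranged(u["remission"][d], f"utilities.remission.{d}") for d in u["remission"]},
        relapse={d: _parse_ranged(u["relapse"][d], f"utilities.relapse.{d}") for d in u["relapse"]},
        failure=_parse_ranged(u["failure"], "utilities.failure"),
        dialysis=_parse_ranged(u["dialysis"], "utilities.dialysis"),
        transplant=_parse_ranged(u["transplant"], "utilities.transplant"),
    )


def _parse_components(node, key: str) -> CostComponents:
    return CostComponents(
        direct_medical=_parse_ranged(node["direct_medical"], f"{key}.direct_medical"),
        direct_nonmedical=_parse_ranged(node["direct_nonmedical"], f"{key}.direct_nonmedical"),
        indirect=_parse_ranged(node["indirect"], f"{key}.indirect"),
    )


def _parse_costs(doc: Mapping) -> CostTable:
    c = doc["costs"]
    return CostTable(
        induction={d: _parse_components(c["induction"][d], f"costs.induction.{d}") for d in c["induction"]},
        remission={d: _parse_components(c["remission"][d], f"costs.remission.{d}") for d in c["remission"]},
        relapse={d: _parse_components(c["relapse"][d], f"costs.relapse.{d}") for d in c["relapse"]},
        failure=_parse_components(c["failure"], "costs.failure"),
        dialysis=_parse_components(c["dialysis"], "costs.dialysis"),
        transplant=_parse_components(c["transplant"], "costs.transplant"),
        kt_entry_cost=_parse_ranged(c["kt_entry_cost"], "costs.kt_entry_cost"),
    )


def _parse_settings(doc: Mapping) -> EconomicSettings:
    e = dict(doc.get("economics", {}))
    valid = {f.name for f in fields(EconomicSettings)}
    unknown = set(e) - valid
    if unknown:
        raise ParameterError(f"unknown economics keys: {sorted(unknown)}")
    return EconomicSettings(**e)


def load_parameters(path: Optional[str | Path] = None) -> ParameterSet:
    """Read a parameter config file and return a validated :class:`ParameterSet`.

    With ``path=None`` the packaged base-case defaults are used.  Missing
    ``utilities``/``costs`` sections fall back to the packaged synthetic
    tables (generated deterministically), with a logged warning.
    """
    resolved = Path(path) if path is not None else default_config_path()
    resolved = resolved.resolve()
    logger.info("loading parameters from %s", resolved)
    if not resolved.exists():
        raise FileNotFoundError(f"parameter file not found: {resolved}")
    try:
        doc = yaml.safe_load(resolved.read_text())
    except yaml.YAMLError as exc:
        raise ParameterError(f"could not parse {resolved}: {exc}") from exc
    if not isinstance(doc, Mapping) or "transitions" not in doc:
        raise ParameterError(f"{resolved} has no 'transitions' section")

    transitions = _parse_transitions(doc)

    if "utilities" in doc and "costs" in doc:
        utilities = _parse_utilities(doc)
        costs = _parse_costs(doc)
    else:
        from .synthetic_data import SyntheticConfig, generate_cost_utility_tables

        logger.warning(
            "config %s omits cost/utility sections; falling back to packaged "
            "synthetic defaults",
            resolved,
        )
        utilities, costs = generate_cost_utility_tables(SyntheticConfig())
        if "utilities" in doc:
            utilities = _parse_utilities(doc)
        if "costs" in doc:
            costs = _parse_costs(doc)

    settings = _parse_settings(doc)
    return ParameterSet(transitions, utilities, costs, settings).validate()


def load_default_parameters() -> ParameterSet:
    """Shortcut for :func:`load_parameters` on the packaged defaults."""
    return load_parameters(None)
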