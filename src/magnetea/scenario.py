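"""Scenario data model: parameter containers, validation, load/save.

A :class:`ProcessScenario` bundles every number needed to simulate and cost
one plant configuration: fermentation and downstream physics, batch schedule,
purchase prices, factored-cost coefficients, equipment list and finance terms.
All internal economic computation is in USD; price entries may be denominated
in BRL and are converted at the scenario exchange rate when evaluated, so the
exchange rate is a live model parameter rather than a load-time constant.

Units are encoded in field names (``_h`` hours, ``_m3`` cubic metres,
``_mg_l`` mg/L, ``_g_l`` g dry cell weight per litre) and documented in
docs/methods.md.
"""

from __future__ import annotations

import copy
import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterator, Mapping

import yaml

from .errors import ScenarioError, ScenarioValidationError

SINGLE_STAGE = "single_stage"
SEMICONTINUOUS = "semicontinuous"
MODES = (SINGLE_STAGE, SEMICONTINUOUS)

SECTIONS = ("inoculum", "fermentation", "downstream")

USD = "USD"
BRL = "BRL"
CURRENCIES = (USD, BRL)


# ---------------------------------------------------------------------------
# containers


@dataclass
class StoichiometrySpec:
    """Global growth reaction, molar coefficients per published equation.

    Substrate is lactic acid (one 3-carbon molecule per formula unit);
    nitrogen enters as nitrate and ammonium.  The element balance of the
    published coefficients does not close; residuals are reported, never
    forced to zero (see :func:`magnetea.stoichiometry.stoichiometric_yields`).
    """

    substrate: float = 352.0
    nitrate: float = 33.6
    ammonium: float = 133.0
    oxygen: float = 6.46
    ferric_iron: float = 1.25
    biomass: float = 718.4
    water: float = 591.3
    carbon_dioxide: float = 314.0
    # biomass elemental formula, indices per carbon: CH2.06 O0.13 N0.28 Fe0.00174
    biomass_h: float = 2.06
    biomass_o: float = 0.13
    biomass_n: float = 0.28
    biomass_fe: float = 0.00174


@dataclass
class FermentationParams:
    duration_h: float = 42.0
    temperature_c: float = 30.0
    ph_min: float = 6.8
    ph_max: float = 7.0
    mu: float = 0.10                    # specific growth rate, 1/h
    mu_reference: float = 0.10          # mu at which magnetite_yield_mg_l was measured
    aeration_vvm: float = 0.003
    magnetite_yield_mg_l: float = 250.0
    stage2_yield_mg_l: float | None = None   # semicontinuous second stage only
    vessel_volume_m3: float = 29.0
    max_working_fraction: float = 0.80
    initial_volume_m3: float = 15.0
    final_working_volume_m3: float = 26.2854106871673
    harvest_fraction: float | None = None    # semicontinuous only
    inoculum_expansion_factor: float = 10.0
    inoculum_stages: int = 3
    initial_biomass_g_l: float = 0.30   # density after inoculating the main vessel
    target_biomass_g_l: float = 3.5     # substrate-limited density cap
    # medium composition, kg per m3 of medium (process_water in m3 per m3)
    media_recipe: dict[str, float] = field(default_factory=dict)


@dataclass
class DownstreamParams:
    homogenizer_passes: int = 4
    per_pass_lysis_fraction: float = 0.70
    msc_efficiency: float = 0.85        # per-column magnetite capture, both columns
    msc_flowrate_bv_h: float = 3.0
    centrifuge_efficiency: float = 0.90
    urea_concentration_mol_l: float = 4.0
    urea_wash_ratio: float = 0.800328868100478   # m3 wash per m3 lysate processed
    sucrose_per_m3_processed: float = 10.652296946484375  # kg/m3
    buffer_salts_per_kg_product: float = 14.1562          # kg/kg
    product_concentration_mg_ml: float = 1.0


@dataclass
class ScheduleParams:
    annual_operating_time_h: float = 7200.0
    batch_time_h: float = 161.7
    cycle_time_h: float = 46.67
    labor_hours_per_batch: dict[str, float] = field(default_factory=dict)


@dataclass
class Price:
    amount: float
    currency: str = USD
    unit: str = "per kg"


@dataclass
class PriceTable:
    """Purchase prices by material; BRL entries convert at ``exchange_rate``."""

    entries: dict[str, Price] = field(default_factory=dict)
    exchange_rate: float = 5.20         # BRL per USD
    currency: str = USD                 # reporting currency

    def usd(self, material: str) -> float:
        """Unit price of *material* in USD (missing entries raise KeyError)."""
        p = self.entries[material]
        if p.currency == USD:
            return p.amount
        return p.amount / self.exchange_rate


@dataclass
class CostFactors:
    installation_multiplier: float = 4.835918183861542
    working_capital_fraction: float = 0.15
    startup_fraction: float = 0.061015570532186814
    maintenance_fraction: float = 0.025
    tax_insurance_fraction: float = 0.008
    overhead_fraction: float = 0.008941211557827875
    depreciation_life_years: float = 12.0
    salvage_fraction: float = 0.05
    qc_fraction_of_labor: float = 0.15
    labor_rate: float = 130.0
    labor_rate_currency: str = BRL      # per hour
    utilities_per_batch: float = 2600.0
    utilities_currency: str = BRL
    capacity_labor_exponent: float = 0.25   # labor scales sub-linearly with capacity


@dataclass
class FinanceParams:
    target_payback_years: float = 5.0
    income_tax_rate: float = 0.40
    price_floor_usd_kg: float = 30_000.0
    price_ceiling_usd_kg: float = 120_000.0


@dataclass
class EquipmentItem:
    name: str
    section: str
    size: float
    size_units: str
    base_size: float
    base_cost_usd: float
    scale_exponent: float = 0.6

    @property
    def purchase_cost_usd(self) -> float:
        from .costing import scale_equipment_cost

        return scale_equipment_cost(
            self.base_cost_usd, self.base_size, self.size, self.scale_exponent
        )


@dataclass
class ProcessScenario:
    name: str = "base_single"
    mode: str = SINGLE_STAGE
    fermentation: FermentationParams = field(default_factory=FermentationParams)
    downstream: DownstreamParams = field(default_factory=DownstreamParams)
    schedule: ScheduleParams = field(default_factory=ScheduleParams)
    prices: PriceTable = field(default_factory=PriceTable)
    cost_factors: CostFactors = field(default_factory=CostFactors)
    finance: FinanceParams = field(default_factory=FinanceParams)
    equipment: list[EquipmentItem] = field(default_factory=list)
    stoichiometry: StoichiometrySpec = field(default_factory=StoichiometrySpec)
    provenance: dict[str, str] = field(default_factory=dict)
    overrides: list[str] = field(default_factory=list)

    def copy(self) -> "ProcessScenario":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# validation


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def _positive(report, value, path):
    if value is None or not value > 0:
        report.violations.append(f"{path}: must be strictly positive, got {value!r}")


def _fraction(report, value, path, open_low=True, closed_high=True):
    lo_ok = value > 0 if open_low else value >= 0
    hi_ok = value <= 1 if closed_high else value < 1
    if not (lo_ok and hi_ok):
        report.violations.append(f"{path}: fraction out of range (0, 1], got {value!r}")


def validate_scenario(scenario: ProcessScenario) -> ValidationReport:
    """Check every hard invariant; soft limits become warnings.

    Hard violations: non-positive volumes/times/rates/prices, efficiencies or
    fractions outside (0, 1], final working volume above the vessel volume,
    missing semicontinuous sub-block, malformed price grid.  Soft: working
    volume above the stated maximum working fraction of the vessel.
    """
    r = ValidationReport()
    s = scenario
    if s.mode not in MODES:
        r.violations.append(f"mode: unknown mode {s.mode!r}, expected one of {MODES}")

    f = s.fermentation
    for name in ("duration_h", "mu", "mu_reference", "aeration_vvm",
                 "magnetite_yield_mg_l", "vessel_volume_m3", "initial_volume_m3",
                 "final_working_volume_m3", "initial_biomass_g_l",
                 "target_biomass_g_l"):
        _positive(r, getattr(f, name), f"fermentation.{name}")
    _fraction(r, f.max_working_fraction, "fermentation.max_working_fraction")
    if f.inoculum_stages < 1:
        r.violations.append("fermentation.inoculum_stages: must be >= 1")
    if f.inoculum_expansion_factor <= 1:
        r.violations.append(
            "fermentation.inoculum_expansion_factor: must exceed 1, got "
            f"{f.inoculum_expansion_factor!r}"
        )
    if f.final_working_volume_m3 > f.vessel_volume_m3:
        r.violations.append(
            "fermentation.final_working_volume_m3: exceeds vessel volume "
            f"({f.final_working_volume_m3} > {f.vessel_volume_m3} m3)"
        )
    elif f.final_working_volume_m3 > f.max_working_fraction * f.vessel_volume_m3:
        r.warnings.append(
            "fermentation.final_working_volume_m3: working volume "
            f"{f.final_working_volume_m3:.2f} m3 exceeds the maximum working "
            f"fraction {f.max_working_fraction:.0%} of the {f.vessel_volume_m3} m3 "
            "vessel"
        )
    if f.target_biomass_g_l <= f.initial_biomass_g_l:
        r.violations.append(
            "fermentation.target_biomass_g_l: must exceed initial_biomass_g_l"
        )
    for comp, conc in f.media_recipe.items():
        if conc < 0:
            r.violations.append(f"fermentation.media_recipe.{comp}: negative amount")

    if s.mode == SEMICONTINUOUS:
        if f.harvest_fraction is None or f.stage2_yield_mg_l is None:
            r.violations.append(
                "fermentation: semicontinuous mode requires harvest_fraction "
                "and stage2_yield_mg_l"
            )
        else:
            if not (0 < f.harvest_fraction < 1):
                r.violations.append(
                    "fermentation.harvest_fraction: must lie in (0, 1), got "
                    f"{f.harvest_fraction!r}"
                )
            if f.stage2_yield_mg_l >= f.magnetite_yield_mg_l:
                r.warnings.append(
                    "fermentation.stage2_yield_mg_l: second-stage yield not below "
                    "first-stage yield (reported decline is >50%)"
                )

    d = s.downstream
    if d.homogenizer_passes < 1:
        r.violations.append("downstream.homogenizer_passes: must be >= 1")
    _fraction(r, d.per_pass_lysis_fraction, "downstream.per_pass_lysis_fraction")
    _fraction(r, d.msc_efficiency, "downstream.msc_efficiency")
    _fraction(r, d.centrifuge_efficiency, "downstream.centrifuge_efficiency")
    for name in ("msc_flowrate_bv_h", "urea_concentration_mol_l",
                 "product_concentration_mg_ml"):
        _positive(r, getattr(d, name), f"downstream.{name}")
    for name in ("urea_wash_ratio", "sucrose_per_m3_processed",
                 "buffer_salts_per_kg_product"):
        if getattr(d, name) < 0:
            r.violations.append(f"downstream.{name}: negative")

    sc = s.schedule
    for name in ("annual_operating_time_h", "batch_time_h", "cycle_time_h"):
        _positive(r, getattr(sc, name), f"schedule.{name}")
    if sc.cycle_time_h > sc.batch_time_h:
        r.violations.append(
            f"schedule.cycle_time_h: cycle time {sc.cycle_time_h} h exceeds batch "
            f"time {sc.batch_time_h} h"
        )
    if sc.annual_operating_time_h < sc.batch_time_h:
        r.violations.append(
            "schedule.annual_operating_time_h: shorter than one batch time"
        )
    for sect, hours in sc.labor_hours_per_batch.items():
        if hours < 0:
            r.violations.append(f"schedule.labor_hours_per_batch.{sect}: negative")

    _positive(r, s.prices.exchange_rate, "prices.exchange_rate")
    for mat, price in s.prices.entries.items():
        _positive(r, price.amount, f"prices.entries.{mat}.amount")
        if price.currency not in CURRENCIES:
            r.violations.append(
                f"prices.entries.{mat}.currency: unknown currency {price.currency!r}"
            )

    cf = s.cost_factors
    _positive(r, cf.installation_multiplier, "cost_factors.installation_multiplier")
    _positive(r, cf.depreciation_life_years, "cost_factors.depreciation_life_years")
    _positive(r, cf.labor_rate, "cost_factors.labor_rate")
    for name in ("working_capital_fraction", "startup_fraction",
                 "maintenance_fraction", "tax_insurance_fraction",
                 "overhead_fraction", "salvage_fraction", "qc_fraction_of_labor"):
        if getattr(cf, name) < 0:
            r.violations.append(f"cost_factors.{name}: negative fraction")
    if cf.utilities_per_batch < 0:
        r.violations.append("cost_factors.utilities_per_batch: negative")

    fin = s.finance
    _positive(r, fin.target_payback_years, "finance.target_payback_years")
    if not (0 <= fin.income_tax_rate < 1):
        r.violations.append(
            f"finance.income_tax_rate: must lie in [0, 1), got {fin.income_tax_rate!r}"
        )
    if not fin.price_floor_usd_kg < fin.price_ceiling_usd_kg:
        r.violations.append("finance: price grid lower bound must be below upper")

    for i, item in enumerate(s.equipment):
        path = f"equipment[{i}]({item.name})"
        if item.section not in SECTIONS:
            r.violations.append(f"{path}.section: unknown section {item.section!r}")
        _positive(r, item.size, f"{path}.size")
        _positive(r, item.base_size, f"{path}.base_size")
        _positive(r, item.base_cost_usd, f"{path}.base_cost_usd")
        if not (0 < item.scale_exponent <= 1):
            r.violations.append(f"{path}.scale_exponent: must lie in (0, 1]")

    st = s.stoichiometry
    for name in ("substrate", "nitrate", "ammonium", "oxygen", "ferric_iron",
                 "biomass", "water", "carbon_dioxide"):
        _positive(r, getattr(st, name), f"stoichiometry.{name}")
    return r


# ---------------------------------------------------------------------------
# serialization

_NESTED = {
    "fermentation": FermentationParams,
    "downstream": DownstreamParams,
    "schedule": ScheduleParams,
    "cost_factors": CostFactors,
    "finance": FinanceParams,
    "stoichiometry": StoichiometrySpec,
}


def scenario_to_dict(scenario: ProcessScenario) -> dict:
    return dataclasses.asdict(scenario)


def scenario_from_dict(doc: Mapping[str, Any]) -> ProcessScenario:
    """Rebuild a scenario from :func:`scenario_to_dict` output (strict keys)."""
    doc = dict(doc)
    kwargs: dict[str, Any] = {}
    for key, cls in _NESTED.items():
        if key in doc:
            sub = dict(doc.pop(key))
            _check_keys(cls, sub, key)
            kwargs[key] = cls(**sub)
    if "prices" in doc:
        sub = dict(doc.pop("prices"))
        entries = {
            mat: Price(**dict(p)) for mat, p in dict(sub.pop("entries", {})).items()
        }
        _check_keys(PriceTable, sub, "prices")
        kwargs["prices"] = PriceTable(entries=entries, **sub)
    if "equipment" in doc:
        kwargs["equipment"] = [
            EquipmentItem(**dict(item)) for item in doc.pop("equipment")
        ]
    for key in ("name", "mode", "provenance", "overrides"):
        if key in doc:
            kwargs[key] = doc.pop(key)
    if doc:
        raise ScenarioError(f"unknown scenario key(s): {sorted(doc)}")
    return ProcessScenario(**kwargs)


def _check_keys(cls, mapping: Mapping[str, Any], path: str) -> None:
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ScenarioError(
            f"unknown key(s) under '{path}': {sorted(unknown)}; "
            f"known keys: {sorted(known)}"
        )


def save_scenario(scenario: ProcessScenario, path: str | Path) -> None:
    """Persist a scenario as YAML (JSON also accepted on load)."""
    path = Path(path)
    with path.open("w") as fh:
        yaml.safe_dump(scenario_to_dict(scenario), fh, sort_keys=False)


def _apply_overrides(scenario: ProcessScenario, overrides: Mapping[str, Any],
                     prefix: str = "") -> None:
    """Recursively merge an override mapping into *scenario*, recording paths.

    Unknown keys are hard errors (a silently ignored typo in a price name
    would corrupt the costing), reported with the full dotted path.
    """
    for key, value in overrides.items():
        path = f"{prefix}{key}"
        target = scenario if not prefix else _resolve(scenario, prefix.rstrip("."))
        if dataclasses.is_dataclass(target) and not isinstance(target, type):
            if not any(f.name == key for f in dataclasses.fields(target)):
                raise ScenarioError(f"unknown key '{path}' in scenario document")
            current = getattr(target, key)
            if isinstance(value, Mapping) and (
                dataclasses.is_dataclass(current) or isinstance(current, dict)
            ):
                _apply_overrides(scenario, value, prefix=f"{path}.")
            else:
                setattr(target, key, value)
                scenario.overrides.append(f"{path}={value!r}")
        elif isinstance(target, dict):
            # dict leaves (media recipe, labor hours, price entries)
            if isinstance(value, Mapping) and isinstance(target.get(key), Price):
                for pk, pv in value.items():
                    if pk not in ("amount", "currency", "unit"):
                        raise ScenarioError(f"unknown key '{path}.{pk}'")
                    setattr(target[key], pk, pv)
                    scenario.overrides.append(f"{path}.{pk}={pv!r}")
            else:
                target[key] = value
                scenario.overrides.append(f"{path}={value!r}")
        else:
            raise ScenarioError(f"cannot override '{path}' (not a parameter block)")


def _resolve(scenario: ProcessScenario, dotted: str):
    obj: Any = scenario
    for part in dotted.split("."):
        obj = obj[part] if isinstance(obj, dict) else getattr(obj, part)
    return obj


def load_scenario(source: str | Path | Mapping[str, Any]) -> ProcessScenario:
    """Load a scenario document (YAML/JSON path or mapping).

    The document names a packaged base fixture (``base: base_single`` by
    default); every other key overrides the corresponding fixture value and is
    recorded in ``scenario.overrides``.  Unknown keys and invariant breaches
    raise :class:`ScenarioError` / :class:`ScenarioValidationError` with the
    offending path.
    """
    from .fixtures import builtin_fixture

    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        try:
            doc = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ScenarioError(f"cannot parse scenario document: {exc}") from exc
    else:
        doc = dict(source)
    if doc is None:
        doc = {}
    if not isinstance(doc, Mapping):
        raise ScenarioError("scenario document must be a mapping")

    doc = dict(doc)
    base = doc.pop("base", "base_single")
    scenario = builtin_fixture(base)
    _apply_overrides(scenario, doc)
    report = validate_scenario(scenario)
    if not report.ok:
        raise ScenarioValidationError(report.violations)
    return scenario


# ---------------------------------------------------------------------------
# provenance helpers


def leaf_paths(scenario: ProcessScenario) -> Iterator[str]:
    """Yield the dotted path of every scalar parameter in the scenario."""

    def walk(obj: Any, prefix: str) -> Iterator[str]:
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            for f in dataclasses.fields(obj):
                yield from walk(getattr(obj, f.name), f"{prefix}{f.name}.")
        elif isinstance(obj, dict):
            for key, value in obj.items():
                yield from walk(value, f"{prefix}{key}.")
        elif isinstance(obj, (list, tuple)):
            for i, value in enumerate(obj):
                yield from walk(value, f"{prefix}{i}.")
        else:
            yield prefix.rstrip(".")

    for f in dataclasses.fields(scenario):
        if f.name in ("provenance", "overrides", "name"):
            continue
        yield from walk(getattr(scenario, f.name), f"{f.name}.")


def provenance_frame(scenario: ProcessScenario):
    """Provenance table (parameter, value, source) as a DataFrame."""
    import pandas as pd

    rows = []
    for path in leaf_paths(scenario):
        try:
            value = _resolve(scenario, path)
        except (AttributeError, KeyError):
            value = None
        rows.append(
            {
                "parameter": path,
                "value": value,
                "source": scenario.provenance.get(path, ""),
            }
        )
    return pd.DataFrame(rows)


def scenario_hash(scenario: ProcessScenario) -> str:
    """Stable content hash of a scenario (for run manifests)."""
    import hashlib

    blob = json.dumps(scenario_to_dict(scenario), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
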