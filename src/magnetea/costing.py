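"""Factored capital estimation and annual operating cost assembly.

Capital follows the classical factored method: purchased equipment costs
(power-law scaled from base sizes) sum to the equipment total; an
installation multiplier turns that into direct fixed capital (total plant
cost); working-capital and startup fractions complete the total investment.

Operating cost is direct (materials, labor, utilities, QC) plus indirect
(maintenance, straight-line depreciation, taxes/overhead — all fractions of
direct fixed capital).  Every cost is attributed to a plant section
(inoculum / fermentation / downstream): materials by where they are consumed,
labor and QC by operator hours, utilities to fermentation (aeration, steam),
indirect by each section's share of installed equipment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import MagneteaError, PricingError
from .scenario import (
    BRL,
    SECTIONS,
    CostFactors,
    EquipmentItem,
    PriceTable,
    ProcessScenario,
)
from .scheduling import ScheduleResult


def scale_equipment_cost(
    base_cost: float, base_size: float, size: float, exponent: float
) -> float:
    """Power-law equipment costing: base_cost * (size/base_size)**exponent."""
    if size <= 0 or base_size <= 0:
        raise MagneteaError("equipment sizes must be positive")
    return base_cost * (size / base_size) ** exponent


@dataclass
class CapitalSummary:
    equipment_total_usd: float
    total_plant_cost_usd: float         # direct fixed capital
    working_capital_usd: float
    startup_cost_usd: float
    total_investment_usd: float
    equipment_by_section: dict[str, float] = field(default_factory=dict)

    @property
    def section_shares(self) -> dict[str, float]:
        return {
            s: v / self.equipment_total_usd
            for s, v in self.equipment_by_section.items()
        }


def capital_investment(
    items: list[EquipmentItem], cf: CostFactors
) -> CapitalSummary:
    if not items:
        raise MagneteaError("capital estimation requires a non-empty equipment list")
    by_section = {s: 0.0 for s in SECTIONS}
    for item in items:
        by_section[item.section] = (
            by_section.get(item.section, 0.0) + item.purchase_cost_usd
        )
    equipment_total = sum(by_section.values())
    dfc = cf.installation_multiplier * equipment_total
    working = cf.working_capital_fraction * dfc
    startup = cf.startup_fraction * dfc
    return CapitalSummary(
        equipment_total_usd=equipment_total,
        total_plant_cost_usd=dfc,
        working_capital_usd=working,
        startup_cost_usd=startup,
        total_investment_usd=dfc + working + startup,
        equipment_by_section=by_section,
    )


@dataclass
class MaterialsCost:
    total_usd: float
    by_section: dict[str, float]
    by_material: dict[str, dict[str, float]]    # section -> material -> USD/yr


def materials_cost(
    annual_demand: dict[str, dict[str, float]], prices: PriceTable
) -> MaterialsCost:
    """Price an annual demand map (section -> material -> kg or m3), in USD."""
    by_section: dict[str, float] = {}
    by_material: dict[str, dict[str, float]] = {}
    for section, demand in annual_demand.items():
        section_costs = {}
        for material, amount in demand.items():
            try:
                unit_price = prices.usd(material)
            except KeyError:
                raise PricingError(
                    f"no price entry for material '{material}' "
                    f"(section '{section}')"
                ) from None
            section_costs[material] = amount * unit_price
        by_material[section] = section_costs
        by_section[section] = sum(section_costs.values())
    return MaterialsCost(
        total_usd=sum(by_section.values()),
        by_section=by_section,
        by_material=by_material,
    )


def labor_cost(
    schedule: ScheduleResult, cf: CostFactors, exchange_rate: float
) -> tuple[float, float]:
    """Annual labor and QC cost, USD/yr (QC is a fraction of labor)."""
    rate_usd = (
        cf.labor_rate / exchange_rate
        if cf.labor_rate_currency == BRL
        else cf.labor_rate
    )
    labor = schedule.annual_labor_hours * rate_usd
    return labor, cf.qc_fraction_of_labor * labor


def utilities_cost(
    n_batches: int, cf: CostFactors, exchange_rate: float
) -> float:
    per_batch = (
        cf.utilities_per_batch / exchange_rate
        if cf.utilities_currency == BRL
        else cf.utilities_per_batch
    )
    return n_batches * per_batch


@dataclass
class OperatingSummary:
    direct: dict[str, float]            # materials, labor, utilities, qc
    indirect: dict[str, float]          # maintenance, depreciation, taxes_overhead
    total_usd_per_year: float
    by_section: dict[str, float]
    materials: MaterialsCost

    @property
    def direct_total(self) -> float:
        return sum(self.direct.values())

    @property
    def indirect_total(self) -> float:
        return sum(self.indirect.values())

    @property
    def indirect_share(self) -> float:
        return self.indirect_total / self.total_usd_per_year


def indirect_costs(cap: CapitalSummary, cf: CostFactors) -> dict[str, float]:
    """Maintenance, straight-line depreciation and taxes/overhead, USD/yr."""
    dfc = cap.total_plant_cost_usd
    depreciation = dfc * (1.0 - cf.salvage_fraction) / cf.depreciation_life_years
    return {
        "maintenance": cf.maintenance_fraction * dfc,
        "depreciation": depreciation,
        "taxes_overhead": (cf.tax_insurance_fraction + cf.overhead_fraction) * dfc,
    }


def operating_cost_summary(
    materials: MaterialsCost,
    schedule: ScheduleResult,
    cap: CapitalSummary,
    cf: CostFactors,
    exchange_rate: float,
) -> OperatingSummary:
    labor, qc = labor_cost(schedule, cf, exchange_rate)
    utilities = utilities_cost(schedule.batches_per_year, cf, exchange_rate)
    direct = {
        "materials": materials.total_usd,
        "labor": labor,
        "utilities": utilities,
        "qc": qc,
    }
    indirect = indirect_costs(cap, cf)
    total = sum(direct.values()) + sum(indirect.values())

    # section attribution
    by_section = {s: 0.0 for s in SECTIONS}
    for section, cost in materials.by_section.items():
        by_section[section] += cost
    total_hours = schedule.annual_labor_hours
    for section, hours in schedule.labor_hours_by_section.items():
        if total_hours > 0:
            by_section[section] += (labor + qc) * hours / total_hours
    by_section["fermentation"] += utilities
    indirect_total = sum(indirect.values())
    for section, share in cap.section_shares.items():
        by_section[section] += indirect_total * share

    return OperatingSummary(
        direct=direct,
        indirect=indirect,
        total_usd_per_year=total,
        by_section=by_section,
        materials=materials,
    )


def annual_demand(
    batch_demand: dict[str, dict[str, float]], n_batches: int
) -> dict[str, dict[str, float]]:
    return {
        section: {mat: amount * n_batches for mat, amount in demand.items()}
        for section, demand in batch_demand.items()
    }


def cost_frame(cap: CapitalSummary, op: OperatingSummary, mode: str):
    """Cost report mirroring the economic summary rows, one row per item."""
    import pandas as pd

    rows = [
        ("capital_investment_musd", cap.total_investment_usd / 1e6),
        ("total_plant_cost_musd", cap.total_plant_cost_usd / 1e6),
        ("equipment_cost_musd", cap.equipment_total_usd / 1e6),
        ("working_capital_musd", cap.working_capital_usd / 1e6),
        ("startup_cost_musd", cap.startup_cost_usd / 1e6),
        ("operating_cost_musd_per_year", op.total_usd_per_year / 1e6),
        ("direct_operating_musd_per_year", op.direct_total / 1e6),
        ("indirect_operating_musd_per_year", op.indirect_total / 1e6),
    ]
    rows += [(f"direct.{k}_musd_per_year", v / 1e6) for k, v in op.direct.items()]
    rows += [(f"indirect.{k}_musd_per_year", v / 1e6) for k, v in op.indirect.items()]
    rows += [
        (f"section.{k}_musd_per_year", v / 1e6) for k, v in op.by_section.items()
    ]
    return pd.DataFrame(rows, columns=["item", "value"]).assign(mode=mode)


def equipment_frame(scenario: ProcessScenario):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "name": item.name,
                "section": item.section,
                "size": item.size,
                "size_units": item.size_units,
                "purchase_cost_usd": item.purchase_cost_usd,
            }
            for item in scenario.equipment
        ]
    )
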