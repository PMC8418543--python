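"""Packaged base-case scenarios with calibrated, frozen parameter values.

Two fixtures are shipped: ``base_single`` (single-stage fed-batch) and
``base_semicontinuous`` (two-stage repeated-harvest operation).  Process
parameters (yields, times, efficiencies, vessel sizes) are the published
base-case values of the source techno-economic study.  Quantities the source
study does not print — equipment purchase costs, installation and indirect
cost factors, labor hours, the medium recipe and wash ratios — were
calibrated ONCE so that the two fixtures reproduce the study's published
economic summary (annual operating cost, capital investment, unit production
cost, material cost share structure), then frozen here as literals.  The
calibration algebra is reproducible via :mod:`magnetea.calibrate`.

Every parameter carries a provenance note: either the published source
location or the calibration target it was tuned to.
"""

from __future__ import annotations

from .errors import ScenarioError
from .scenario import (
    BRL,
    SEMICONTINUOUS,
    SINGLE_STAGE,
    CostFactors,
    DownstreamParams,
    EquipmentItem,
    FermentationParams,
    FinanceParams,
    Price,
    PriceTable,
    ProcessScenario,
    ScheduleParams,
    StoichiometrySpec,
)

FIXTURE_VERSION = "1.0"

# -- calibrated working volumes (recovered-product basis) -------------------
# Overall recovery = (1 - 0.3^4) * 0.85 * 0.90 * 0.85 = 0.644982975.
# Single stage: 640 kg/yr over 151 batches at 250 mg/L.
# Semicontinuous: 640 kg/yr over 82 batches at 250 + 110 mg/L, 90% harvest
# (total harvested = 0.36 kg magnetite per m3 working volume).
V_SINGLE_M3 = 26.2854106871673
V_SEMI_M3 = 33.613626471563876
INITIAL_SEMI_M3 = 19.181910569105693    # same initial/final ratio as single stage

# -- fermentation medium recipe, kg per m3 (process_water: m3 per m3) -------
# Lactic-acid concentration calibrated so lactic acid carries ~64% of the
# fermentation-section material cost at the fixture prices.
MEDIA_RECIPE = {
    "lactic_acid": 51.274375473483246,
    "ferric_chloride": 3.0,
    "sodium_nitrate": 4.0,
    "ammonium_chloride": 5.0,
    "yeast_extract": 4.5,
    "mineral_salts": 7.0,
    "process_water": 1.0,
}

# -- purchase prices (Brazilian-market, BRL at 5.20 BRL/USD) ----------------
PRICES_BRL = {
    "lactic_acid": (9.10, "per kg"),
    "urea": (2.08, "per kg"),
    "ferric_chloride": (4.68, "per kg"),
    "sodium_nitrate": (3.12, "per kg"),
    "ammonium_chloride": (2.34, "per kg"),
    "yeast_extract": (31.20, "per kg"),
    "mineral_salts": (10.40, "per kg"),
    "process_water": (10.40, "per m3"),
    "sucrose": (2.60, "per kg"),
    "buffer_salts": (10.40, "per kg"),
}
EXCHANGE_RATE = 5.20    # BRL per USD

# -- labor (annual single-stage labor cost calibrated to 1.09x semicontinuous)
LABOR_RATE_BRL_H = 130.0
LABOR_HOURS_SINGLE = {          # 94.7073 h/batch over 151 batches
    "inoculum": 15.0,
    "fermentation": 45.0,
    "downstream": 34.70728476821192,
}
LABOR_HOURS_SEMI = {            # 160 h/batch over 82 batches
    "inoculum": 20.0,
    "fermentation": 90.0,
    "downstream": 50.0,
}
UTILITIES_BRL_BATCH_SINGLE = 2600.0
UTILITIES_BRL_BATCH_SEMI = 3510.0

# -- equipment lists (fermenter pinned at 30.6% / 38.2% of equipment totals,
#    totals pinned at the published 8.898 M / 12.888 M USD) -----------------
EQUIPMENT_SINGLE = [
    ("seed bioreactor train", "inoculum", 1.5, "m3", 1_600_000.0),
    ("main bioreactor", "fermentation", 29.0, "m3", 2_722_788.0),
    ("media preparation tank", "fermentation", 30.0, "m3", 700_000.0),
    ("media sterilizer", "fermentation", 6.0, "m3/h", 450_000.0),
    ("media storage tank", "fermentation", 30.0, "m3", 350_000.0),
    ("air compressor", "fermentation", 5.2, "m3/min", 400_000.0),
    ("air filtration skid", "fermentation", 5.2, "m3/min", 200_000.0),
    ("high-pressure homogenizer", "downstream", 3.0, "m3/h", 950_000.0),
    ("disk-stack centrifuge", "downstream", 4.0, "m3/h", 1_150_000.0),
    ("magnetic separation columns (2)", "downstream", 1.0, "m3 bed", 300_000.0),
    ("CIP skid", "downstream", 1.0, "unit", 75_212.0),
]
EQUIPMENT_SEMI = [
    ("seed bioreactor train", "inoculum", 1.9, "m3", 1_800_000.0),
    ("main bioreactor", "fermentation", 37.0, "m3", 4_923_216.0),
    ("media preparation tank", "fermentation", 40.0, "m3", 1_000_000.0),
    ("media sterilizer", "fermentation", 8.0, "m3/h", 650_000.0),
    ("media storage tank", "fermentation", 40.0, "m3", 500_000.0),
    ("air compressor", "fermentation", 6.7, "m3/min", 550_000.0),
    ("air filtration skid", "fermentation", 6.7, "m3/min", 300_000.0),
    ("high-pressure homogenizer", "downstream", 4.0, "m3/h", 1_300_000.0),
    ("disk-stack centrifuge", "downstream", 5.0, "m3/h", 1_450_000.0),
    ("magnetic separation columns (2)", "downstream", 1.3, "m3 bed", 330_000.0),
    ("CIP skid", "downstream", 1.0, "unit", 84_784.0),
]

# -- calibrated cost factors ------------------------------------------------
COST_FACTORS_SINGLE = dict(
    installation_multiplier=4.835918183861542,      # 43.03 M / 8.898 M
    working_capital_fraction=0.15,
    startup_fraction=0.061015570532186814,          # closes 52.11 M investment
    maintenance_fraction=0.025,
    tax_insurance_fraction=0.008,
    overhead_fraction=0.008941211557827875,         # closes 6.64 M/yr operating
    depreciation_life_years=12.0,
    salvage_fraction=0.05,
    qc_fraction_of_labor=0.15,
    labor_rate=LABOR_RATE_BRL_H,
    labor_rate_currency=BRL,
    utilities_per_batch=UTILITIES_BRL_BATCH_SINGLE,
    utilities_currency=BRL,
    capacity_labor_exponent=0.25,
)
COST_FACTORS_SEMI = dict(
    installation_multiplier=5.1225946617008065,     # 66.02 M / 12.888 M
    working_capital_fraction=0.15,
    startup_fraction=0.05963344441078469,           # closes 79.86 M investment
    maintenance_fraction=0.002,
    tax_insurance_fraction=0.0008,
    overhead_fraction=0.0013751615459827457,        # closes 7.15 M/yr operating
    depreciation_life_years=12.0,
    salvage_fraction=0.05,
    qc_fraction_of_labor=0.15,
    labor_rate=LABOR_RATE_BRL_H,
    labor_rate_currency=BRL,
    utilities_per_batch=UTILITIES_BRL_BATCH_SEMI,
    utilities_currency=BRL,
    capacity_labor_exponent=0.25,
)


def _price_table() -> PriceTable:
    entries = {
        mat: Price(amount=amount, currency=BRL, unit=unit)
        for mat, (amount, unit) in PRICES_BRL.items()
    }
    return PriceTable(entries=entries, exchange_rate=EXCHANGE_RATE)


def _equipment(rows) -> list[EquipmentItem]:
    return [
        EquipmentItem(
            name=name,
            section=section,
            size=size,
            size_units=units,
            base_size=size,
            base_cost_usd=cost,
            scale_exponent=0.6,
        )
        for name, section, size, units, cost in rows
    ]


_SRC_FERM = "source study, fermentation parameter table"
_SRC_DOWN = "source study, downstream parameter table"
_SRC_SUMMARY = "source study, bioprocess/economic summary table"
_SRC_TEXT = "source study, running text"
_CAL = "calibrated fixture: "


def _provenance(mode: str) -> dict[str, str]:
    col = "single-stage column" if mode == SINGLE_STAGE else "semicontinuous column"
    p = {
        "mode": "source study, the two simulated operating modes",
        "fermentation.duration_h": _SRC_FERM + " (42 h)",
        "fermentation.temperature_c": _SRC_FERM + " (30 C)",
        "fermentation.ph_min": _SRC_FERM + " (pH 6.8-7.0)",
        "fermentation.ph_max": _SRC_FERM + " (pH 6.8-7.0)",
        "fermentation.mu": _SRC_TEXT + " (specific growth rate 0.10; the "
        "parameter table prints 0.01, treated as a typographical discrepancy)",
        "fermentation.mu_reference": _SRC_TEXT + " (yield measured at mu = 0.10)",
        "fermentation.aeration_vvm": _SRC_FERM + " (0.003 vvm)",
        "fermentation.magnetite_yield_mg_l": _SRC_FERM + " (250 mg/L)",
        "fermentation.stage2_yield_mg_l": _CAL + "satisfies the reported >50% "
        "second-stage yield decline while closing the 640 kg/yr throughput",
        "fermentation.vessel_volume_m3": _SRC_FERM + " (29 m3 main fermenter)"
        if mode == SINGLE_STAGE
        else _CAL + "proportionally larger vessel for the semicontinuous volume",
        "fermentation.max_working_fraction": _SRC_FERM + " (80% maximum)",
        "fermentation.initial_volume_m3": _SRC_TEXT + " (~15 m3 initial medium)"
        if mode == SINGLE_STAGE
        else _CAL + "same initial/final volume ratio as single stage",
        "fermentation.final_working_volume_m3": _CAL + "640 kg/yr recovered "
        f"product over the published batch count ({col})",
        "fermentation.harvest_fraction": _SRC_TEXT
        + " (90% of the medium removed to downstream)",
        "fermentation.inoculum_expansion_factor": _SRC_TEXT
        + " (seed expansion factor of 10)",
        "fermentation.inoculum_stages": _SRC_TEXT
        + " (three consecutive seed bioreactors)",
        "fermentation.initial_biomass_g_l": _CAL + "post-inoculation cell density; "
        "with the density cap it realizes the reported growth-rate sensitivity",
        "fermentation.target_biomass_g_l": _CAL + "substrate-limited density cap, "
        "realistic for high-density MSR-1 cultures",
        "downstream.homogenizer_passes": _SRC_DOWN + " (4 passes)",
        "downstream.per_pass_lysis_fraction": _CAL + "standard high-pressure "
        "homogenization practice; >=99% lysis in 4 passes",
        "downstream.msc_efficiency": _SRC_DOWN + " (85% binding capacity, "
        "applied per column)",
        "downstream.msc_flowrate_bv_h": _SRC_DOWN + " (3 bed volumes/h)",
        "downstream.centrifuge_efficiency": _SRC_DOWN + " (90% sedimentation)",
        "downstream.urea_concentration_mol_l": _SRC_TEXT + " (4 M urea wash)",
        "downstream.urea_wash_ratio": _CAL + "urea carries ~87% of downstream "
        "material cost and total materials close at 1,472 USD/kg product",
        "downstream.sucrose_per_m3_processed": _CAL + "sucrose syrup added "
        "before centrifugation, proportional to processed lysate",
        "downstream.buffer_salts_per_kg_product": _CAL + "phosphate buffer for "
        "the 1 mg/mL product colloid",
        "downstream.product_concentration_mg_ml": _SRC_TEXT
        + " (1 mg/mL product suspension)",
        "schedule.annual_operating_time_h": _SRC_SUMMARY + " (7,200 h)",
        "schedule.batch_time_h": _SRC_SUMMARY + f" (recipe batch time, {col})",
        "schedule.cycle_time_h": _SRC_SUMMARY + f" (recipe cycle time, {col})",
        "prices.exchange_rate": _SRC_TEXT + " (US$ 1 = R$ 5.20, June 2020)",
        "prices.currency": "package convention: all results reported in USD",
        "finance.target_payback_years": _SRC_TEXT + " (fixed 5-year payback)",
        "finance.income_tax_rate": _CAL + "after-tax payback convention that "
        "reproduces the published minimum selling prices",
        "finance.price_floor_usd_kg": _SRC_TEXT
        + " (hypothetical selling prices from US$ 30 thousand/kg)",
        "finance.price_ceiling_usd_kg": _SRC_TEXT
        + " (hypothetical selling prices up to US$ 120 thousand/kg)",
        "cost_factors.installation_multiplier": _CAL + "published total plant "
        "cost over published equipment cost",
        "cost_factors.working_capital_fraction": _CAL + "standard factored-TEA "
        "working capital share of direct fixed capital",
        "cost_factors.startup_fraction": _CAL + "closes the published total "
        "capital investment",
        "cost_factors.maintenance_fraction": _CAL + "indirect cost decomposition",
        "cost_factors.tax_insurance_fraction": _CAL + "indirect cost decomposition",
        "cost_factors.overhead_fraction": _CAL + "closes the published annual "
        "operating cost",
        "cost_factors.depreciation_life_years": _CAL + "straight-line life "
        "consistent with both published operating-cost totals",
        "cost_factors.salvage_fraction": _CAL + "standard salvage assumption",
        "cost_factors.qc_fraction_of_labor": _CAL + "QC/QA charged as a labor "
        "surcharge",
        "cost_factors.labor_rate": _CAL + "Brazilian-market operator rate (BRL/h)",
        "cost_factors.labor_rate_currency": "package convention",
        "cost_factors.utilities_per_batch": _CAL + "aggregate steam/power per "
        "batch; utilities are a minor cost share",
        "cost_factors.utilities_currency": "package convention",
        "cost_factors.capacity_labor_exponent": _CAL + "sub-linear labor "
        "scaling with plant capacity",
    }
    for comp in MEDIA_RECIPE:
        p[f"fermentation.media_recipe.{comp}"] = (
            _CAL + "medium recipe standing in for the unavailable supplementary "
            "media table; lactic acid concentration sets its 64% cost share"
        )
    for mat in PRICES_BRL:
        p[f"prices.entries.{mat}.amount"] = (
            _CAL + "Brazilian-market commodity price list standing in for the "
            "unavailable supplementary price table"
        )
        p[f"prices.entries.{mat}.currency"] = "package convention (BRL)"
        p[f"prices.entries.{mat}.unit"] = "package convention"
    for sect in ("inoculum", "fermentation", "downstream"):
        p[f"schedule.labor_hours_per_batch.{sect}"] = (
            _CAL + "operator hours per batch; single-stage annual labor cost "
            "calibrated to 1.09x semicontinuous"
        )
    rows = EQUIPMENT_SINGLE if mode == SINGLE_STAGE else EQUIPMENT_SEMI
    for i, (name, _, _, _, _) in enumerate(rows):
        note = (
            _CAL + "equipment list standing in for the unavailable supplementary "
            "equipment tables; fermenter pinned at the published 30.6%/38.2% "
            "share, totals at the published equipment cost"
        )
        for fld in ("name", "section", "size", "size_units", "base_size",
                    "base_cost_usd", "scale_exponent"):
            p[f"equipment.{i}.{fld}"] = note
    for fld in ("substrate", "nitrate", "ammonium", "oxygen", "ferric_iron",
                "biomass", "water", "carbon_dioxide", "biomass_h", "biomass_o",
                "biomass_n", "biomass_fe"):
        p[f"stoichiometry.{fld}"] = (
            _SRC_TEXT + " (global growth equation and biomass elemental formula, "
            "coefficients adopted verbatim; species reconstructed from context)"
        )
    return p


def base_single() -> ProcessScenario:
    ferm = FermentationParams(
        mu=0.10,
        magnetite_yield_mg_l=250.0,
        vessel_volume_m3=29.0,
        initial_volume_m3=15.0,
        final_working_volume_m3=V_SINGLE_M3,
        media_recipe=dict(MEDIA_RECIPE),
    )
    sched = ScheduleParams(
        annual_operating_time_h=7200.0,
        batch_time_h=161.7,
        cycle_time_h=46.67,
        labor_hours_per_batch=dict(LABOR_HOURS_SINGLE),
    )
    s = ProcessScenario(
        name="base_single",
        mode=SINGLE_STAGE,
        fermentation=ferm,
        downstream=DownstreamParams(),
        schedule=sched,
        prices=_price_table(),
        cost_factors=CostFactors(**COST_FACTORS_SINGLE),
        finance=FinanceParams(),
        equipment=_equipment(EQUIPMENT_SINGLE),
        stoichiometry=StoichiometrySpec(),
        provenance=_provenance(SINGLE_STAGE),
    )
    return s


def base_semicontinuous() -> ProcessScenario:
    ferm = FermentationParams(
        mu=0.10,
        magnetite_yield_mg_l=250.0,
        stage2_yield_mg_l=110.0,
        vessel_volume_m3=37.0,
        initial_volume_m3=INITIAL_SEMI_M3,
        final_working_volume_m3=V_SEMI_M3,
        harvest_fraction=0.90,
        media_recipe=dict(MEDIA_RECIPE),
    )
    sched = ScheduleParams(
        annual_operating_time_h=7200.0,
        batch_time_h=193.1,
        cycle_time_h=85.75,
        labor_hours_per_batch=dict(LABOR_HOURS_SEMI),
    )
    s = ProcessScenario(
        name="base_semicontinuous",
        mode=SEMICONTINUOUS,
        fermentation=ferm,
        downstream=DownstreamParams(),
        schedule=sched,
        prices=_price_table(),
        cost_factors=CostFactors(**COST_FACTORS_SEMI),
        finance=FinanceParams(),
        equipment=_equipment(EQUIPMENT_SEMI),
        stoichiometry=StoichiometrySpec(),
        provenance=_provenance(SEMICONTINUOUS),
    )
    return s


_FIXTURES = {
    "base_single": base_single,
    "base_semicontinuous": base_semicontinuous,
}


def available_fixtures() -> list[str]:
    return sorted(_FIXTURES)


def builtin_fixture(name: str) -> ProcessScenario:
    """Return a fresh, fully validated copy of a packaged base-case scenario."""
    try:
        builder = _FIXTURES[name]
    except KeyError:
        raise ScenarioError(
            f"unknown fixture {name!r}; available fixtures: {available_fixtures()}"
        ) from None
    return builder()
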