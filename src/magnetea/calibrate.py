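"""One-time calibration that produced the frozen fixture constants.

The source study prints its process parameters and its economic results but
not the intermediate cost model (equipment lists, installation and indirect
factors, medium recipe, labor hours).  This module re-derives every
calibrated fixture constant algebraically from the published anchors:

* working volumes from the 640 kg/yr recovered throughput, the published
  batch counts and the recovery cascade;
* the medium's lactic-acid concentration from its 64% share of
  fermentation-section material cost;
* the urea wash ratio from urea's 87% share of downstream material cost and
  the 1,472 USD/kg total material cost;
* labor so single-stage annual labor cost is 1.09x semicontinuous;
* installation multipliers, startup and indirect fractions so capital
  investment and annual operating cost close on the published totals.

The calibration ran once; its outputs are frozen in :mod:`magnetea.fixtures`.
:func:`verify_frozen` recomputes everything and confirms the frozen literals
still match, and the ``magnetea calibrate`` CLI writes the constants (with
provenance notes) to YAML for audit.
"""

from __future__ import annotations

import math

from . import fixtures

# published anchors
BATCHES = {"single": 151, "semi": 82}
ANNUAL_PRODUCT_KG = 640.0
YIELD_KG_M3 = 0.250
STAGE2_YIELD_KG_M3 = 0.110
HARVEST_FRACTION = 0.90
OPERATING_MUSD = {"single": 6.64, "semi": 7.15}
DFC_MUSD = {"single": 43.03, "semi": 66.02}
EQUIPMENT_MUSD = {"single": 8.898, "semi": 12.888}
INVESTMENT_MUSD = {"single": 52.11, "semi": 79.86}
FERMENTER_SHARE = {"single": 0.306, "semi": 0.382}
MATERIAL_COST_USD_KG_SINGLE = 1472.0
LACTIC_SHARE_FERMENTATION = 0.64
UREA_SHARE_DOWNSTREAM = 0.87
LABOR_RATIO_SINGLE_OVER_SEMI = 1.09
EXCHANGE_RATE = 5.20

UREA_KG_M3_WASH = 4.0 * 60.06           # 4 M urea
SEED_VOLUME_FRACTION = 0.1 + 0.01 + 0.001  # 3 seed stages, factor 10


def overall_recovery() -> float:
    lysed = 1.0 - (1.0 - 0.70) ** 4
    return lysed * 0.85 * 0.90 * 0.85


def calibrate() -> dict:
    """Re-derive every calibrated constant; returns a flat dict of values."""
    rec = overall_recovery()
    out: dict[str, float] = {"overall_recovery": rec}

    # working volumes (recovered-product basis)
    v_single = ANNUAL_PRODUCT_KG / (BATCHES["single"] * YIELD_KG_M3 * rec)
    per_m3_harvest_semi = (
        HARVEST_FRACTION * YIELD_KG_M3
        + (1 - HARVEST_FRACTION) * YIELD_KG_M3
        + STAGE2_YIELD_KG_M3
    )
    v_semi = ANNUAL_PRODUCT_KG / (BATCHES["semi"] * per_m3_harvest_semi * rec)
    out["v_single_m3"] = v_single
    out["v_semi_m3"] = v_semi
    out["initial_semi_m3"] = v_semi * (15.0 / v_single)

    # medium recipe: solve urea wash ratio (87% share) and lactic-acid
    # concentration (64% share) against the 1,472 USD/kg materials total
    usd = {m: brl / EXCHANGE_RATE for m, (brl, _) in fixtures.PRICES_BRL.items()}
    recovered_single = ANNUAL_PRODUCT_KG / BATCHES["single"]
    buffer_cost = 14.1562 * recovered_single * usd["buffer_salts"]
    sucrose_cost = 280.0 * usd["sucrose"]   # fixed sucrose mass per batch
    urea_usd_m3 = UREA_KG_M3_WASH * usd["urea"]
    # urea = share * (urea + sucrose + buffer + wash water)
    wash_total = (
        UREA_SHARE_DOWNSTREAM
        * (sucrose_cost + buffer_cost)
        / (
            (1 - UREA_SHARE_DOWNSTREAM) * urea_usd_m3
            - UREA_SHARE_DOWNSTREAM * usd["process_water"]
        )
    )
    out["urea_wash_ratio"] = wash_total / v_single
    out["sucrose_per_m3_processed"] = 280.0 / v_single
    ds_cost = (
        urea_usd_m3 * wash_total
        + sucrose_cost
        + buffer_cost
        + usd["process_water"] * wash_total
    )
    mat_per_batch = MATERIAL_COST_USD_KG_SINGLE * ANNUAL_PRODUCT_KG / BATCHES["single"]
    medium_single = SEED_VOLUME_FRACTION * 15.0 + v_single
    ferm_per_m3 = (mat_per_batch - ds_cost) / medium_single
    non_lactic = sum(
        conc * usd[comp]
        for comp, conc in fixtures.MEDIA_RECIPE.items()
        if comp != "lactic_acid"
    )
    out["lactic_acid_kg_m3"] = (ferm_per_m3 - non_lactic) / usd["lactic_acid"]
    out["lactic_share"] = (ferm_per_m3 - non_lactic) / ferm_per_m3

    # capital factors
    for mode in ("single", "semi"):
        out[f"installation_multiplier_{mode}"] = (
            DFC_MUSD[mode] / EQUIPMENT_MUSD[mode]
        )
        out[f"startup_fraction_{mode}"] = (
            (INVESTMENT_MUSD[mode] - DFC_MUSD[mode]) / DFC_MUSD[mode] - 0.15
        )
        out[f"fermenter_cost_{mode}_usd"] = (
            FERMENTER_SHARE[mode] * EQUIPMENT_MUSD[mode] * 1e6
        )

    # labor: semicontinuous 160 h/batch chosen; single follows from the 1.09x
    labor_semi_usd = (
        160.0 * BATCHES["semi"] * fixtures.LABOR_RATE_BRL_H / EXCHANGE_RATE
    )
    labor_single_usd = LABOR_RATIO_SINGLE_OVER_SEMI * labor_semi_usd
    out["labor_hours_single_per_batch"] = labor_single_usd / (
        BATCHES["single"] * fixtures.LABOR_RATE_BRL_H / EXCHANGE_RATE
    )

    # indirect remainders close the published operating totals
    mat_annual = {"single": MATERIAL_COST_USD_KG_SINGLE * ANNUAL_PRODUCT_KG}
    # semicontinuous materials follow from the same recipe at its volumes
    medium_semi = out["initial_semi_m3"] * SEED_VOLUME_FRACTION + 1.9 * v_semi
    processed_semi = 1.9 * v_semi
    recovered_semi = ANNUAL_PRODUCT_KG / BATCHES["semi"]
    ds_semi = (
        urea_usd_m3 * out["urea_wash_ratio"] * processed_semi
        + out["sucrose_per_m3_processed"] * processed_semi * usd["sucrose"]
        + 14.1562 * recovered_semi * usd["buffer_salts"]
        + usd["process_water"] * out["urea_wash_ratio"] * processed_semi
    )
    mat_annual["semi"] = (ferm_per_m3 * medium_semi + ds_semi) * BATCHES["semi"]
    out["materials_annual_semi_usd"] = mat_annual["semi"]

    utilities = {
        "single": fixtures.UTILITIES_BRL_BATCH_SINGLE
        / EXCHANGE_RATE
        * BATCHES["single"],
        "semi": fixtures.UTILITIES_BRL_BATCH_SEMI / EXCHANGE_RATE * BATCHES["semi"],
    }
    labor = {"single": labor_single_usd, "semi": labor_semi_usd}
    maint_tax = {
        "single": (0.025, 0.008),
        "semi": (0.002, 0.0008),
    }
    for mode in ("single", "semi"):
        direct = mat_annual[mode] + labor[mode] * 1.15 + utilities[mode]
        indirect = OPERATING_MUSD[mode] * 1e6 - direct
        dfc = DFC_MUSD[mode] * 1e6
        depreciation = dfc * 0.95 / 12.0
        maintenance, tax = maint_tax[mode]
        out[f"indirect_share_{mode}"] = indirect / (OPERATING_MUSD[mode] * 1e6)
        out[f"overhead_fraction_{mode}"] = (
            indirect - depreciation
        ) / dfc - maintenance - tax
    return out


#: map of calibrated value -> frozen fixture literal, used by verify_frozen
_FROZEN = {
    "v_single_m3": lambda: fixtures.V_SINGLE_M3,
    "v_semi_m3": lambda: fixtures.V_SEMI_M3,
    "initial_semi_m3": lambda: fixtures.INITIAL_SEMI_M3,
    "lactic_acid_kg_m3": lambda: fixtures.MEDIA_RECIPE["lactic_acid"],
    "urea_wash_ratio": lambda: fixtures.base_single().downstream.urea_wash_ratio,
    "sucrose_per_m3_processed": lambda: (
        fixtures.base_single().downstream.sucrose_per_m3_processed
    ),
    "labor_hours_single_per_batch": lambda: sum(
        fixtures.LABOR_HOURS_SINGLE.values()
    ),
    "installation_multiplier_single": lambda: (
        fixtures.COST_FACTORS_SINGLE["installation_multiplier"]
    ),
    "installation_multiplier_semi": lambda: (
        fixtures.COST_FACTORS_SEMI["installation_multiplier"]
    ),
    "startup_fraction_single": lambda: (
        fixtures.COST_FACTORS_SINGLE["startup_fraction"]
    ),
    "startup_fraction_semi": lambda: fixtures.COST_FACTORS_SEMI["startup_fraction"],
    "overhead_fraction_single": lambda: (
        fixtures.COST_FACTORS_SINGLE["overhead_fraction"]
    ),
    "overhead_fraction_semi": lambda: fixtures.COST_FACTORS_SEMI["overhead_fraction"],
    "fermenter_cost_single_usd": lambda: next(
        row[4] for row in fixtures.EQUIPMENT_SINGLE if row[0] == "main bioreactor"
    ),
    "fermenter_cost_semi_usd": lambda: next(
        row[4] for row in fixtures.EQUIPMENT_SEMI if row[0] == "main bioreactor"
    ),
}


def verify_frozen(rtol: float = 1e-9) -> dict[str, tuple[float, float]]:
    """Recompute the calibration and compare with the frozen fixture literals.

    Returns a mapping name -> (recomputed, frozen) for any mismatch beyond
    *rtol*; an empty dict means the fixtures are faithful to the calibration.
    """
    computed = calibrate()
    mismatches = {}
    for name, frozen_getter in _FROZEN.items():
        frozen = frozen_getter()
        value = computed[name]
        if not math.isclose(value, frozen, rel_tol=rtol, abs_tol=1e-12):
            mismatches[name] = (value, frozen)
    return mismatches
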