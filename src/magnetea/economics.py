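"""Unit cost, cash flow, payback curve and minimum selling price (MSP).

The cash-flow model is simple payback: at a candidate selling price p the
plant earns revenue p x annual product, pays the annual operating cost, and
the after-tax net profit services the total capital investment:

    payback(p) = total_investment / ((p Q - AOC) (1 - tax)).

The MSP is the price at which payback equals the fixed target (5 years),
found by bisection on the configured price grid.  No depreciation add-back
is applied and no discounting is performed (the model is simple payback, not
NPV/IRR); the income-tax rate is exposed in the scenario.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import bisect

from .costing import CapitalSummary, OperatingSummary
from .errors import MagneteaError, SolverError
from .scenario import FinanceParams

#: Published reference costs for chemically synthesized magnetite, carried as
#: static constants for report comparison (USD/kg product; equipment in USD).
REFERENCE_PROCESSES = {
    "co-precipitation (bare magnetite)": {
        "production_cost_usd_kg": 210.0,
        "material_cost_usd_kg": 78.0,
        "equipment_cost_usd": 1_036_000.0,
    },
    "hydrothermal (carbon-coated magnetite)": {
        "production_cost_usd_kg": 4_192.0,
        "material_cost_usd_kg": 1_361.0,
        "equipment_cost_usd": 2_027_000.0,
    },
}


def unit_production_cost(op: OperatingSummary, annual_product_kg: float) -> float:
    """Annual operating cost over annual recovered product, USD/kg."""
    if annual_product_kg <= 0:
        raise MagneteaError("unit cost undefined for zero annual product")
    return op.total_usd_per_year / annual_product_kg


def annual_cash_flow(
    price_usd_kg: float,
    annual_product_kg: float,
    operating_usd_year: float,
    income_tax_rate: float,
) -> dict[str, float]:
    """Revenue, gross and after-tax net profit at a selling price, USD/yr."""
    revenue = price_usd_kg * annual_product_kg
    gross = revenue - operating_usd_year
    tax = max(gross, 0.0) * income_tax_rate
    return {
        "revenue": revenue,
        "gross_profit": gross,
        "income_tax": tax,
        "net_profit": gross - tax,
    }


def payback_time(
    cap: CapitalSummary,
    operating_usd_year: float,
    annual_product_kg: float,
    price_usd_kg: float,
    income_tax_rate: float,
) -> float:
    """Years to repay the total investment; +inf below the break-even price."""
    flow = annual_cash_flow(
        price_usd_kg, annual_product_kg, operating_usd_year, income_tax_rate
    )
    if flow["net_profit"] <= 0:
        return math.inf
    return cap.total_investment_usd / flow["net_profit"]


def payback_curve(
    cap: CapitalSummary,
    operating_usd_year: float,
    annual_product_kg: float,
    fin: FinanceParams,
    n_points: int = 61,
):
    """Payback-vs-price table over the configured price grid (a DataFrame)."""
    import pandas as pd

    prices = np.linspace(fin.price_floor_usd_kg, fin.price_ceiling_usd_kg, n_points)
    rows = [
        {
            "price_usd_kg": p,
            "payback_years": payback_time(
                cap, operating_usd_year, annual_product_kg, p, fin.income_tax_rate
            ),
        }
        for p in prices
    ]
    return pd.DataFrame(rows)


def minimum_selling_price(
    cap: CapitalSummary,
    operating_usd_year: float,
    annual_product_kg: float,
    fin: FinanceParams,
    rtol: float = 1e-6,
    expand_grid: bool = True,
) -> float:
    """Solve payback(price) = target by bisection on the price grid.

    With ``expand_grid`` (the default) a bracket that misses the root is
    widened geometrically first — the MSP of a rescaled or perturbed plant
    can fall outside the configured grid.  With ``expand_grid=False`` a
    missing sign change raises :class:`SolverError` advising grid expansion.
    """
    if fin.target_payback_years <= 0:
        raise MagneteaError("target payback must be positive")

    def objective(price: float) -> float:
        pb = payback_time(
            cap, operating_usd_year, annual_product_kg, price, fin.income_tax_rate
        )
        # payback is +inf below break-even: map to a large positive residual
        # so the bracket check still sees a sign change above break-even
        if math.isinf(pb):
            return 1e9
        return pb - fin.target_payback_years

    lo, hi = fin.price_floor_usd_kg, fin.price_ceiling_usd_kg
    f_lo, f_hi = objective(lo), objective(hi)
    if f_lo * f_hi > 0 and expand_grid:
        # payback(price) decreases from +inf (break-even) to 0, so widening
        # the bracket far enough always recovers a sign change
        for _ in range(60):
            if f_lo > 0 >= f_hi:
                break
            if f_lo <= 0:           # MSP below the floor
                lo /= 2.0
                f_lo = objective(lo)
            if f_hi > 0:            # MSP above the ceiling
                hi *= 2.0
                f_hi = objective(hi)
    if f_lo * f_hi > 0:
        raise SolverError(
            "target payback not bracketed by the price grid "
            f"[{lo:g}, {hi:g}] USD/kg (residuals {f_lo:.3g}, {f_hi:.3g}); "
            "expand the finance price grid"
        )
    return float(bisect(objective, lo, hi, rtol=rtol))


@dataclass
class EconomicSummary:
    unit_production_cost_usd_kg: float
    msp_usd_kg: float
    payback_at_msp_years: float
    annual_product_kg: float
    selling_price_usd_kg: float
    revenue_usd_year: float
    gross_profit_usd_year: float
    income_tax_usd_year: float
    net_profit_usd_year: float
    payback_years: float
    reference_comparisons: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in REFERENCE_PROCESSES.items()}
    )


def economic_summary(
    cap: CapitalSummary,
    op: OperatingSummary,
    annual_product_kg: float,
    fin: FinanceParams,
    selling_price_usd_kg: float | None = None,
) -> EconomicSummary:
    """Assemble the full economic block; price defaults to the solved MSP."""
    msp = minimum_selling_price(
        cap, op.total_usd_per_year, annual_product_kg, fin
    )
    price = msp if selling_price_usd_kg is None else selling_price_usd_kg
    flow = annual_cash_flow(
        price, annual_product_kg, op.total_usd_per_year, fin.income_tax_rate
    )
    return EconomicSummary(
        unit_production_cost_usd_kg=unit_production_cost(op, annual_product_kg),
        msp_usd_kg=msp,
        payback_at_msp_years=payback_time(
            cap, op.total_usd_per_year, annual_product_kg, msp, fin.income_tax_rate
        ),
        annual_product_kg=annual_product_kg,
        selling_price_usd_kg=price,
        revenue_usd_year=flow["revenue"],
        gross_profit_usd_year=flow["gross_profit"],
        income_tax_usd_year=flow["income_tax"],
        net_profit_usd_year=flow["net_profit"],
        payback_years=payback_time(
            cap, op.total_usd_per_year, annual_product_kg, price, fin.income_tax_rate
        ),
    )


def reference_comparison(econ: EconomicSummary, material_cost_usd_kg: float):
    """Production/material cost table alongside the chemical-synthesis rows."""
    import pandas as pd

    rows = [
        {
            "process": "biological-origin magnetic nanoparticles (this model)",
            "production_cost_usd_kg": econ.unit_production_cost_usd_kg,
            "material_cost_usd_kg": material_cost_usd_kg,
        }
    ]
    for name, ref in econ.reference_comparisons.items():
        rows.append(
            {
                "process": name,
                "production_cost_usd_kg": ref["production_cost_usd_kg"],
                "material_cost_usd_kg": ref["material_cost_usd_kg"],
            }
        )
    return pd.DataFrame(rows)
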