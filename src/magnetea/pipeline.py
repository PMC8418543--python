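"""End-to-end pipeline: scenario -> mass balance -> schedule -> costs -> economics."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from . import costing, economics, process, scheduling
from .costing import CapitalSummary, OperatingSummary
from .economics import EconomicSummary
from .errors import ScenarioValidationError
from .process import BatchResult
from .scenario import ProcessScenario, ValidationReport, validate_scenario
from .scheduling import ScheduleResult


@dataclass
class AnalysisResult:
    scenario: ProcessScenario
    validation: ValidationReport
    batch: BatchResult
    schedule: ScheduleResult
    capital: CapitalSummary
    operating: OperatingSummary
    economics: EconomicSummary

    @property
    def unit_cost_usd_kg(self) -> float:
        return self.economics.unit_production_cost_usd_kg

    @property
    def msp_usd_kg(self) -> float:
        return self.economics.msp_usd_kg

    @property
    def material_cost_usd_kg(self) -> float:
        return self.operating.materials.total_usd / self.economics.annual_product_kg


def analyze(
    scenario: ProcessScenario, selling_price_usd_kg: float | None = None
) -> AnalysisResult:
    """Run the full techno-economic chain for one scenario.

    Raises :class:`ScenarioValidationError` on hard invariant breaches;
    soft violations (e.g. working volume above the stated maximum fraction)
    are carried as warnings in the result.
    """
    report = validate_scenario(scenario)
    if not report.ok:
        raise ScenarioValidationError(report.violations)

    batch = process.simulate_batch(scenario)
    batch_time = scheduling.adjusted_batch_time_h(
        scenario.schedule, scenario.fermentation
    )
    n = scheduling.batches_per_year(
        scenario.schedule.annual_operating_time_h,
        batch_time,
        scenario.schedule.cycle_time_h,
    )
    sched = scheduling.annual_production(batch, n, scenario.schedule, batch_time)

    cap = costing.capital_investment(scenario.equipment, scenario.cost_factors)
    demand = costing.annual_demand(batch.material_demand, n)
    mats = costing.materials_cost(demand, scenario.prices)
    op = costing.operating_cost_summary(
        mats, sched, cap, scenario.cost_factors, scenario.prices.exchange_rate
    )
    econ = economics.economic_summary(
        cap, op, sched.annual_product_kg, scenario.finance, selling_price_usd_kg
    )
    return AnalysisResult(
        scenario=scenario,
        validation=report,
        batch=batch,
        schedule=sched,
        capital=cap,
        operating=op,
        economics=econ,
    )


def summary_dict(result: AnalysisResult) -> dict:
    """Flat summary mirroring the published bioprocess/economic summary rows."""
    s = result
    return {
        "mode": s.scenario.mode,
        "annual_operating_time_h": s.scenario.schedule.annual_operating_time_h,
        "batch_time_h": s.schedule.batch_time_h,
        "cycle_time_h": s.schedule.cycle_time_h,
        "batches_per_year": s.schedule.batches_per_year,
        "annual_product_kg": s.schedule.annual_product_kg,
        "annual_produced_kg": s.schedule.annual_produced_kg,
        "capital_investment_musd": s.capital.total_investment_usd / 1e6,
        "total_plant_cost_musd": s.capital.total_plant_cost_usd / 1e6,
        "equipment_cost_musd": s.capital.equipment_total_usd / 1e6,
        "operating_cost_musd_per_year": s.operating.total_usd_per_year / 1e6,
        "indirect_share": s.operating.indirect_share,
        "unit_production_cost_usd_kg": s.unit_cost_usd_kg,
        "material_cost_usd_kg": s.material_cost_usd_kg,
        "msp_usd_kg": s.msp_usd_kg,
        "target_payback_years": s.scenario.finance.target_payback_years,
    }


def summary_frame(result: AnalysisResult):
    import pandas as pd

    d = summary_dict(result)
    return pd.DataFrame(
        [{"item": k, "value": v} for k, v in d.items()]
    )


def write_reports(result: AnalysisResult, outdir: str | Path) -> list[Path]:
    """Write the CSV/JSON report set for one analysis; returns written paths."""
    import json

    from .scenario import provenance_frame

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def _write(frame, name):
        path = outdir / name
        frame.to_csv(path, index=False)
        written.append(path)

    _write(summary_frame(result), "summary.csv")
    _write(
        costing.cost_frame(result.capital, result.operating, result.scenario.mode),
        "operating_breakdown.csv",
    )
    mats = result.operating.materials
    import pandas as pd

    mat_rows = [
        {
            "section": section,
            "material": material,
            "cost_usd_per_year": cost,
            "share_of_section": cost / mats.by_section[section]
            if mats.by_section[section]
            else 0.0,
        }
        for section, items in mats.by_material.items()
        for material, cost in items.items()
    ]
    _write(pd.DataFrame(mat_rows), "materials_breakdown.csv")
    _write(process.stream_frame(result.batch), "stream_table.csv")
    _write(
        scheduling.schedule_frame(result.schedule, result.scenario.mode),
        "schedule.csv",
    )
    _write(costing.equipment_frame(result.scenario), "equipment.csv")
    _write(
        economics.payback_curve(
            result.capital,
            result.operating.total_usd_per_year,
            result.schedule.annual_product_kg,
            result.scenario.finance,
        ),
        "payback_curve.csv",
    )
    _write(
        economics.reference_comparison(
            result.economics, result.material_cost_usd_kg
        ),
        "reference_comparison.csv",
    )
    _write(provenance_frame(result.scenario), "provenance.csv")

    summary_path = outdir / "summary.json"
    with summary_path.open("w") as fh:
        json.dump(summary_dict(result), fh, indent=2, sort_keys=True)
    written.append(summary_path)
    return written
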