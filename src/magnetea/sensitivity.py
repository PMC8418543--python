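"""One-at-a-time sensitivity sweeps and randomized scenario ensembles.

The deterministic sweeps vary a single scenario parameter over a range while
holding everything else at base values and re-run the full pipeline per
point.  The stochastic side draws scenario ensembles around the base case
(triangular perturbations over the same sweep ranges by default, mode at the
base value), rejection-resampling draws that violate scenario invariants, and
summarizes unit cost and MSP as P5/P50/P95 percentiles.  Both are seeded and
reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .errors import MagneteaError
from .pipeline import analyze
from .scenario import ProcessScenario, validate_scenario

DEFAULT_SEED = 42
_CAPACITY = "capacity"   # pseudo-parameter handled via capacity_rescale


# ---------------------------------------------------------------------------
# parameter paths


def get_path(scenario: ProcessScenario, path: str) -> Any:
    obj: Any = scenario
    for part in path.split("."):
        obj = obj[part] if isinstance(obj, dict) else getattr(obj, part)
    return obj


def set_path(scenario: ProcessScenario, path: str, value: Any) -> None:
    parts = path.split(".")
    obj: Any = scenario
    for part in parts[:-1]:
        obj = obj[part] if isinstance(obj, dict) else getattr(obj, part)
    leaf = parts[-1]
    if isinstance(obj, dict):
        if leaf not in obj:
            raise MagneteaError(f"parameter path '{path}' does not resolve")
        obj[leaf] = value
    else:
        if not hasattr(obj, leaf):
            raise MagneteaError(f"parameter path '{path}' does not resolve")
        setattr(obj, leaf, value)


def _apply(base: ProcessScenario, path: str, value: float) -> ProcessScenario:
    scenario = base.copy()
    if path == _CAPACITY:
        return capacity_rescale(scenario, value)
    set_path(scenario, path, value)
    return scenario


# ---------------------------------------------------------------------------
# OAT sweeps


@dataclass
class SweepSpec:
    """One-at-a-time sweep over a dotted parameter path (>= 2 values)."""

    parameter: str
    values: Sequence[float]

    def __post_init__(self):
        if len(self.values) < 2:
            raise MagneteaError("a sweep needs at least two values")


def oat_sweep(spec: SweepSpec, base: ProcessScenario) -> pd.DataFrame:
    """Full pipeline re-run per sweep value; the base row is included.

    Values that violate scenario invariants produce a row-level error record
    and the sweep continues.  MSC efficiency sweeps apply to both columns,
    matching the published sensitivity treatment.
    """
    try:
        base_value = None if spec.parameter == _CAPACITY else get_path(
            base, spec.parameter
        )
    except (AttributeError, KeyError):
        raise MagneteaError(
            f"parameter path '{spec.parameter}' does not resolve"
        ) from None

    values = list(spec.values)
    if spec.parameter == _CAPACITY:
        if 1.0 not in values:
            values = [1.0] + values
    elif base_value is not None and base_value not in values:
        values = [base_value] + values

    rows = []
    for value in values:
        row: dict[str, Any] = {
            "parameter": spec.parameter,
            "value": value,
            "is_base": value == (1.0 if spec.parameter == _CAPACITY else base_value),
        }
        try:
            result = analyze(_apply(base, spec.parameter, value))
            row.update(
                unit_cost_usd_kg=result.unit_cost_usd_kg,
                msp_usd_kg=result.msp_usd_kg,
                operating_cost_usd_year=result.operating.total_usd_per_year,
                annual_product_kg=result.schedule.annual_product_kg,
                error="",
            )
        except MagneteaError as exc:
            row.update(
                unit_cost_usd_kg=math.nan,
                msp_usd_kg=math.nan,
                operating_cost_usd_year=math.nan,
                annual_product_kg=math.nan,
                error=str(exc),
            )
        rows.append(row)
    return pd.DataFrame(rows)


def capacity_rescale(base: ProcessScenario, factor: float) -> ProcessScenario:
    """Scenario for a plant of ``factor`` times the base annual capacity.

    Vessel and working volumes scale linearly (same batch count); equipment is
    resized through its power-law exponents; labor scales sub-linearly with
    the configured capacity-labor exponent; per-batch utilities scale with
    volume.  Schedule times are unchanged.
    """
    if factor <= 0:
        raise MagneteaError(f"capacity factor must be positive, got {factor}")
    s = base.copy()
    f = s.fermentation
    for name in ("vessel_volume_m3", "initial_volume_m3", "final_working_volume_m3"):
        setattr(f, name, getattr(f, name) * factor)
    for item in s.equipment:
        item.size = item.size * factor
    labor_scale = factor ** s.cost_factors.capacity_labor_exponent
    s.schedule.labor_hours_per_batch = {
        sect: hours * labor_scale
        for sect, hours in s.schedule.labor_hours_per_batch.items()
    }
    s.cost_factors.utilities_per_batch *= factor
    s.name = f"{base.name}@capacity={factor:g}"
    return s


#: Default perturbation ranges mirroring the published one-at-a-time sweeps
#: (triangular distributions, mode at the base value).
DEFAULT_SWEEP_RANGES: dict[str, tuple[float, float]] = {
    "prices.entries.lactic_acid.amount": (4.55, 13.65),      # BRL/kg
    "prices.entries.urea.amount": (0.26, 3.90),              # BRL/kg (0.05-0.75 USD)
    "prices.exchange_rate": (4.0, 6.5),                      # BRL per USD
    "fermentation.mu": (0.07, 0.13),                         # 1/h
    "fermentation.magnetite_yield_mg_l": (80.0, 350.0),      # mg/L
    "downstream.msc_efficiency": (0.65, 0.95),
    _CAPACITY: (0.5, 2.0),
}


@dataclass
class Perturbation:
    family: str         # "triangular" or "uniform"
    low: float
    mode: float
    high: float


@dataclass
class ScenarioEnsemble:
    """Seeded random scenario ensemble around a base case."""

    base: ProcessScenario
    perturbations: dict[str, Perturbation] = field(default_factory=dict)
    seed: int = DEFAULT_SEED
    draws: int = 1000

    def __post_init__(self):
        if self.draws < 1:
            raise MagneteaError("ensemble needs at least one draw")
        if not self.perturbations:
            self.perturbations = default_perturbations(self.base)


def default_perturbations(base: ProcessScenario) -> dict[str, Perturbation]:
    out = {}
    for path, (low, high) in DEFAULT_SWEEP_RANGES.items():
        mode = 1.0 if path == _CAPACITY else float(get_path(base, path))
        out[path] = Perturbation("triangular", low, mode, high)
    return out


def _draw(rng: np.random.Generator, p: Perturbation) -> float:
    if p.low == p.high:     # degenerate: every draw equals the mode
        return p.mode
    if p.family == "triangular":
        return float(rng.triangular(p.low, p.mode, p.high))
    if p.family == "uniform":
        return float(rng.uniform(p.low, p.high))
    raise MagneteaError(f"unknown distribution family {p.family!r}")


def generate_scenario_ensemble(
    spec: ScenarioEnsemble,
) -> tuple[list[ProcessScenario], int]:
    """Draw ``spec.draws`` scenarios; returns (scenarios, rejected_count).

    Deterministic given the seed: draws are made parameter-by-parameter in
    sorted path order within each draw.  Draws violating scenario invariants
    are rejection-resampled (the resample consumes fresh randomness, keeping
    the stream aligned).
    """
    rng = np.random.default_rng(spec.seed)
    paths = sorted(spec.perturbations)
    scenarios: list[ProcessScenario] = []
    rejected = 0
    for _ in range(spec.draws):
        for _attempt in range(100):
            scenario = spec.base.copy()
            capacity = 1.0
            for path in paths:
                value = _draw(rng, spec.perturbations[path])
                if path == _CAPACITY:
                    capacity = value
                else:
                    set_path(scenario, path, value)
            if capacity != 1.0:
                scenario = capacity_rescale(scenario, capacity)
            if validate_scenario(scenario).ok:
                scenarios.append(scenario)
                break
            rejected += 1
        else:
            raise MagneteaError(
                "could not draw a valid scenario in 100 attempts; "
                "check the perturbation ranges"
            )
    return scenarios, rejected


def evaluate_ensemble(scenarios: list[ProcessScenario]) -> pd.DataFrame:
    """Unit cost / MSP / operating cost per ensemble member."""
    rows = []
    for i, scenario in enumerate(scenarios):
        result = analyze(scenario)
        rows.append(
            {
                "draw": i,
                "unit_cost_usd_kg": result.unit_cost_usd_kg,
                "msp_usd_kg": result.msp_usd_kg,
                "operating_cost_usd_year": result.operating.total_usd_per_year,
            }
        )
    return pd.DataFrame(rows)


def monte_carlo_summary(
    results: pd.DataFrame, seed: int | None = None, draws: int | None = None
) -> pd.DataFrame:
    """P5/P50/P95 of unit cost and MSP (linear-interpolation percentiles)."""
    if len(results) == 0:
        raise MagneteaError("empty ensemble results")
    rows = []
    for metric in ("unit_cost_usd_kg", "msp_usd_kg"):
        p5, p50, p95 = np.percentile(
            results[metric].to_numpy(), [5, 50, 95], method="linear"
        )
        rows.append(
            {
                "metric": metric,
                "p5": p5,
                "p50": p50,
                "p95": p95,
                "seed": seed,
                "draws": len(results) if draws is None else draws,
            }
        )
    return pd.DataFrame(rows)
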