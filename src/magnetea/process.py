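"""Per-batch mass balance: inoculum train, fermentation, downstream recovery.

The fermentation model is deliberately aggregate: the pH-coupled feed is a
total-feed mass balance (the feed volume is the difference between final and
initial working volume, its composition the medium recipe), not a closed-loop
controller, because only per-batch totals enter the economics.  Growth is
exponential at the specific rate ``mu`` from the post-inoculation density up
to a substrate-limited density cap; magnetite accumulates at a constant
volumetric rate during the remaining production window of the fixed
fermentation duration, so slower-growing cultures trade production time for
growth time (this is the growth-rate sensitivity channel).

Downstream is a four-stage recovery cascade — high-pressure homogenizer,
magnetic separation column (MSC), disk-stack centrifuge, second MSC — in
which every stage conserves magnetite exactly: captured + waste = input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import MagneteaError
from .scenario import (
    SEMICONTINUOUS,
    DownstreamParams,
    FermentationParams,
    ProcessScenario,
    StoichiometrySpec,
)
from .stoichiometry import metabolic_demands_kg

MG_L_TO_KG_M3 = 1e-3
UREA_MOLAR_MASS = 60.06  # g/mol


@dataclass
class Stream:
    """Mass flow at one unit operation (kg per batch, volume m3 per batch)."""

    operation: str
    section: str
    masses_kg: dict[str, float] = field(default_factory=dict)
    volume_m3: float = 0.0

    def mass(self, component: str) -> float:
        return self.masses_kg.get(component, 0.0)


@dataclass
class BatchResult:
    """Complete per-batch mass balance of one plant cycle."""

    mode: str
    magnetite_produced_kg: float
    magnetite_recovered_kg: float
    biomass_produced_kg: float
    media_volume_m3: float
    processed_volume_m3: float          # lysate volume through downstream
    product_volume_m3: float
    # section -> material -> amount (kg, or m3 for waters)
    material_demand: dict[str, dict[str, float]] = field(default_factory=dict)
    stream_table: list[Stream] = field(default_factory=list)
    stage_recoveries: dict[str, float] = field(default_factory=dict)
    metabolic_demands_kg: dict[str, float] = field(default_factory=dict)

    @property
    def overall_recovery(self) -> float:
        return self.magnetite_recovered_kg / self.magnetite_produced_kg


# ---------------------------------------------------------------------------
# upstream


def simulate_inoculum_train(fp: FermentationParams) -> list[float]:
    """Seed-stage working volumes (m3), smallest first.

    A geometric series below the main fermenter's initial charge: with charge
    15 m3, factor 10 and 3 stages this is [0.015, 0.15, 1.5] m3, the final
    seed sitting one expansion factor under the initial charge.
    """
    if fp.inoculum_expansion_factor <= 1:
        raise MagneteaError(
            "inoculum train: expansion factor must exceed 1, got "
            f"{fp.inoculum_expansion_factor}"
        )
    if fp.inoculum_stages < 1:
        raise MagneteaError("inoculum train: need at least one seed stage")
    f = fp.inoculum_expansion_factor
    return [
        fp.initial_volume_m3 / f ** (fp.inoculum_stages - k)
        for k in range(fp.inoculum_stages)
    ]


def growth_time_h(fp: FermentationParams) -> float:
    """Time to grow from the inoculation density to the density cap, h."""
    return math.log(fp.target_biomass_g_l / fp.initial_biomass_g_l) / fp.mu


def production_window_h(fp: FermentationParams, mu: float | None = None) -> float:
    """Magnetite production window: fermentation time left after growth, h."""
    mu = fp.mu if mu is None else mu
    t_growth = math.log(fp.target_biomass_g_l / fp.initial_biomass_g_l) / mu
    return max(fp.duration_h - t_growth, 0.0)


def effective_yield_factor(fp: FermentationParams) -> float:
    """Scale factor on the nominal magnetite titer at the scenario's mu.

    The nominal titer is specified at ``mu_reference``; magnetite accumulates
    at a constant volumetric rate during the production window, so the titer
    scales with the window length.  Equal to 1 when mu == mu_reference.
    """
    ref = production_window_h(fp, fp.mu_reference)
    if ref <= 0:
        raise MagneteaError(
            "fermentation: no production window at the reference growth rate"
        )
    return production_window_h(fp) / ref


def _media_demand(fp: FermentationParams, volumes: dict[str, float]) -> dict:
    """Medium component masses per section from the recipe (kg, water m3)."""
    demand: dict[str, dict[str, float]] = {}
    for section, volume in volumes.items():
        demand[section] = {
            comp: conc * volume for comp, conc in fp.media_recipe.items()
        }
    return demand


def _fermentation_result(
    fp: FermentationParams,
    st: StoichiometrySpec,
    produced_kg: float,
    harvest_volumes: list[float],
    media_per_stage: float,
    mode: str,
) -> BatchResult:
    seeds = simulate_inoculum_train(fp)
    seed_volume = sum(seeds)
    media_volume = seed_volume + media_per_stage
    biomass = fp.target_biomass_g_l * fp.final_working_volume_m3  # g/L*m3 == kg
    demand = _media_demand(
        fp, {"inoculum": seed_volume, "fermentation": media_per_stage}
    )
    processed = sum(harvest_volumes)
    result = BatchResult(
        mode=mode,
        magnetite_produced_kg=produced_kg,
        magnetite_recovered_kg=produced_kg,  # downstream not yet applied
        biomass_produced_kg=biomass,
        media_volume_m3=media_volume,
        processed_volume_m3=processed,
        product_volume_m3=0.0,
        material_demand=demand,
        metabolic_demands_kg=metabolic_demands_kg(st, biomass),
    )
    result.stream_table.append(
        Stream(
            operation="fermenter harvest",
            section="fermentation",
            masses_kg={"magnetite": produced_kg, "biomass": biomass},
            volume_m3=processed,
        )
    )
    return result


def simulate_fed_batch(
    fp: FermentationParams, st: StoichiometrySpec
) -> BatchResult:
    """Single-stage fed-batch: one fill-grow-produce-harvest cycle.

    Magnetite produced = effective titer x final working volume; biomass grows
    exponentially (amplification e^(mu t)) until the substrate-limited density
    cap.  Feed volume is final minus initial working volume.  Stoichiometric
    nutrient floors are recorded alongside the (excess) recipe demand.
    """
    if fp.mu <= 0:
        raise MagneteaError(f"fermentation: mu must be positive, got {fp.mu}")
    if fp.final_working_volume_m3 > fp.vessel_volume_m3:
        raise MagneteaError(
            "fermentation: final working volume exceeds the vessel volume"
        )
    yield_kg_m3 = fp.magnetite_yield_mg_l * MG_L_TO_KG_M3 * effective_yield_factor(fp)
    produced = yield_kg_m3 * fp.final_working_volume_m3
    return _fermentation_result(
        fp,
        st,
        produced_kg=produced,
        harvest_volumes=[fp.final_working_volume_m3],
        media_per_stage=fp.final_working_volume_m3,
        mode="single_stage",
    )


def simulate_semicontinuous(
    fp: FermentationParams, st: StoichiometrySpec
) -> BatchResult:
    """Two-stage repeated-harvest operation from a single inoculation.

    Stage 1 runs as a fed-batch; ``harvest_fraction`` of the broth goes to
    downstream and the volume is restored with fresh medium.  Stage 2 inherits
    the retained magnetite, adds its own (lower) titer, and is harvested
    completely.  Fresh medium per batch is therefore roughly twice the
    single-stage amount while the harvested product is less than twice.
    """
    if fp.harvest_fraction is None or fp.stage2_yield_mg_l is None:
        raise MagneteaError(
            "semicontinuous: harvest_fraction and stage2_yield_mg_l are required"
        )
    if not (0 < fp.harvest_fraction < 1):
        raise MagneteaError(
            f"semicontinuous: harvest fraction must lie in (0,1), got "
            f"{fp.harvest_fraction}"
        )
    if fp.mu <= 0:
        raise MagneteaError(f"fermentation: mu must be positive, got {fp.mu}")
    if fp.final_working_volume_m3 > fp.vessel_volume_m3:
        raise MagneteaError(
            "fermentation: final working volume exceeds the vessel volume"
        )
    factor = effective_yield_factor(fp)
    v = fp.final_working_volume_m3
    h = fp.harvest_fraction
    y1 = fp.magnetite_yield_mg_l * MG_L_TO_KG_M3 * factor
    y2 = fp.stage2_yield_mg_l * MG_L_TO_KG_M3 * factor

    stage1_magnetite = y1 * v
    harvest1 = h * stage1_magnetite
    retained = (1 - h) * stage1_magnetite
    harvest2 = retained + y2 * v          # stage 2 fully harvested
    produced = harvest1 + harvest2        # == v * (y1 + y2)

    fresh_stage2 = h * v                  # restore the harvested volume
    result = _fermentation_result(
        fp,
        st,
        produced_kg=produced,
        harvest_volumes=[h * v, v],
        media_per_stage=v + fresh_stage2,
        mode=SEMICONTINUOUS,
    )
    result.stage_recoveries["stage1_harvest_kg"] = harvest1
    result.stage_recoveries["stage2_harvest_kg"] = harvest2
    return result


# ---------------------------------------------------------------------------
# downstream


def lysed_fraction(dp: DownstreamParams) -> float:
    """Cumulative cell lysis over the homogenizer passes: 1 - (1-f)^n."""
    return 1.0 - (1.0 - dp.per_pass_lysis_fraction) ** dp.homogenizer_passes


def run_downstream(fermented: BatchResult, dp: DownstreamParams) -> BatchResult:
    """Apply the recovery cascade homogenizer -> MSC1 -> centrifuge -> MSC2.

    Each stage splits its magnetite input into captured and waste with exact
    conservation; magnetite in unlysed cells leaves with the homogenizer
    waste.  Urea (at the wash molarity), sucrose and wash water scale with the
    processed lysate volume; buffer salts with the product mass.  The product
    is a 1 mg/mL colloid, so product volume = recovered mass / concentration.
    """
    for name in ("per_pass_lysis_fraction", "msc_efficiency",
                 "centrifuge_efficiency"):
        if getattr(dp, name) <= 0:
            raise MagneteaError(
                f"downstream: {name} = 0 is a modelling mistake, not a scenario"
            )
    produced = fermented.magnetite_produced_kg
    if produced <= 0:
        raise MagneteaError("downstream: fermented stream has no magnetite")

    volume = fermented.processed_volume_m3
    lysed = lysed_fraction(dp)
    stages = [
        ("high-pressure homogenizer", lysed),
        ("magnetic separation column 1", dp.msc_efficiency),
        ("disk-stack centrifuge", dp.centrifuge_efficiency),
        ("magnetic separation column 2", dp.msc_efficiency),
    ]
    result = fermented
    current = produced
    for operation, efficiency in stages:
        captured = current * efficiency
        waste = current - captured
        result.stream_table.append(
            Stream(
                operation=operation,
                section="downstream",
                masses_kg={
                    "magnetite_in": current,
                    "magnetite_captured": captured,
                    "magnetite_waste": waste,
                },
                volume_m3=volume,
            )
        )
        result.stage_recoveries[operation] = efficiency
        current = captured

    recovered = current
    result.magnetite_recovered_kg = recovered
    result.product_volume_m3 = recovered / (dp.product_concentration_mg_ml * 1.0)

    wash_volume = dp.urea_wash_ratio * volume
    # mol/L * g/mol = g/L = kg/m3; times m3 of wash gives kg of urea
    urea_kg = dp.urea_concentration_mol_l * UREA_MOLAR_MASS * wash_volume
    result.material_demand["downstream"] = {
        "urea": urea_kg,
        "sucrose": dp.sucrose_per_m3_processed * volume,
        "buffer_salts": dp.buffer_salts_per_kg_product * recovered,
        "process_water": wash_volume,
    }
    result.stream_table.append(
        Stream(
            operation="product formulation",
            section="downstream",
            masses_kg={"magnetite": recovered},
            volume_m3=result.product_volume_m3,
        )
    )
    return result


def simulate_batch(scenario: ProcessScenario) -> BatchResult:
    """Full per-batch mass balance for a scenario (fermentation + downstream)."""
    if scenario.mode == SEMICONTINUOUS:
        fermented = simulate_semicontinuous(
            scenario.fermentation, scenario.stoichiometry
        )
    else:
        fermented = simulate_fed_batch(scenario.fermentation, scenario.stoichiometry)
    return run_downstream(fermented, scenario.downstream)


def batch_material_demand(batch: BatchResult) -> dict[str, float]:
    """Total per-batch demand by material (kg; waters m3), across sections."""
    totals: dict[str, float] = {}
    for section_demand in batch.material_demand.values():
        for material, amount in section_demand.items():
            totals[material] = totals.get(material, 0.0) + amount
    return totals


def stream_frame(batch: BatchResult):
    """Stream table as a tidy DataFrame (operation, component, mass, volume)."""
    import pandas as pd

    rows = []
    for stream in batch.stream_table:
        for component, mass in stream.masses_kg.items():
            rows.append(
                {
                    "operation": stream.operation,
                    "section": stream.section,
                    "component": component,
                    "mass_kg": mass,
                    "volume_m3": stream.volume_m3,
                }
            )
    return pd.DataFrame(rows)
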