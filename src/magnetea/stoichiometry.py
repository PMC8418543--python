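"""Growth stoichiometry: yield coefficients and element-balance residuals.

The global growth reaction for *M. gryphiswaldense* MSR-1 is carried with the
published molar coefficients

    352 lactate + 33.6 NO3- + 133 NH4+ + 6.46 O2 + 1.25 Fe3+
        -> 718.4 biomass + 591.3 H2O + 314 CO2

with biomass CH2.06 O0.13 N0.28 Fe0.00174 (indices per carbon).  The printed
equation does not balance element-by-element; the residuals are computed and
reported as data, never silently corrected, because downstream economics only
consume the coefficient ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import MagneteaError
from .scenario import StoichiometrySpec

# atomic masses, g/mol
_MASS = {"C": 12.011, "H": 1.008, "O": 15.999, "N": 14.007, "Fe": 55.845}

# element composition per formula unit of each reaction species; the substrate
# is lactic acid C3H6O3 (one 3-carbon molecule per stoichiometric unit)
_SPECIES = {
    "substrate": {"C": 3, "H": 6, "O": 3},
    "nitrate": {"N": 1, "O": 3},
    "ammonium": {"N": 1, "H": 4},
    "oxygen": {"O": 2},
    "ferric_iron": {"Fe": 1},
    "water": {"H": 2, "O": 1},
    "carbon_dioxide": {"C": 1, "O": 2},
}

_REACTANTS = ("substrate", "nitrate", "ammonium", "oxygen", "ferric_iron")
_PRODUCTS = ("water", "carbon_dioxide")

MOLAR_MASS_MAGNETITE = 3 * _MASS["Fe"] + 4 * _MASS["O"]  # Fe3O4, ~231.5 g/mol
MOLAR_MASS_LACTIC = 3 * _MASS["C"] + 6 * _MASS["H"] + 3 * _MASS["O"]


def biomass_molar_mass(st: StoichiometrySpec) -> float:
    """Molar mass of one C-mole of biomass, g/mol."""
    return (
        _MASS["C"]
        + st.biomass_h * _MASS["H"]
        + st.biomass_o * _MASS["O"]
        + st.biomass_n * _MASS["N"]
        + st.biomass_fe * _MASS["Fe"]
    )


@dataclass
class YieldCoefficients:
    """Molar yield ratios of the global growth reaction plus balance residuals."""

    biomass_per_substrate: float
    fe_per_biomass: float
    o2_per_substrate: float
    co2_per_substrate: float
    nitrogen_per_biomass: float
    residuals_mol: dict[str, float]     # element -> (in - out), mol per formula unit


def stoichiometric_yields(st: StoichiometrySpec) -> YieldCoefficients:
    """Yield-coefficient ratios of the printed coefficients, with residuals.

    Residuals are reported per element as reactant-side minus product-side
    moles for the equation as printed; a nonzero residual is surfaced, not
    raised, because the published equation is adopted verbatim.
    """
    if st.substrate == 0:
        raise MagneteaError("stoichiometry: substrate coefficient must be nonzero")

    biomass_elements = {
        "C": 1.0,
        "H": st.biomass_h,
        "O": st.biomass_o,
        "N": st.biomass_n,
        "Fe": st.biomass_fe,
    }
    residuals: dict[str, float] = {}
    for element in _MASS:
        inflow = sum(
            getattr(st, sp) * _SPECIES[sp].get(element, 0) for sp in _REACTANTS
        )
        outflow = st.biomass * biomass_elements[element] + sum(
            getattr(st, sp) * _SPECIES[sp].get(element, 0) for sp in _PRODUCTS
        )
        residuals[element] = inflow - outflow

    return YieldCoefficients(
        biomass_per_substrate=st.biomass / st.substrate,
        fe_per_biomass=st.ferric_iron / st.biomass,
        o2_per_substrate=st.oxygen / st.substrate,
        co2_per_substrate=st.carbon_dioxide / st.substrate,
        nitrogen_per_biomass=(st.nitrate + st.ammonium) / st.biomass,
        residuals_mol=residuals,
    )


def metabolic_demands_kg(st: StoichiometrySpec, biomass_kg: float) -> dict[str, float]:
    """Minimum stoichiometric consumption (kg) to grow *biomass_kg* of cells.

    These are metabolic floors used as a consistency check against the medium
    recipe, which deliberately supplies each nutrient in excess.
    """
    y = stoichiometric_yields(st)
    biomass_mol = biomass_kg * 1000.0 / biomass_molar_mass(st)
    substrate_mol = biomass_mol / y.biomass_per_substrate
    return {
        "substrate": substrate_mol * MOLAR_MASS_LACTIC / 1000.0,
        "oxygen": substrate_mol * y.o2_per_substrate * 2 * _MASS["O"] / 1000.0,
        "ferric_iron": biomass_mol * y.fe_per_biomass * _MASS["Fe"] / 1000.0,
        "nitrogen": biomass_mol * y.nitrogen_per_biomass * _MASS["N"] / 1000.0,
        "carbon_dioxide_out": substrate_mol
        * y.co2_per_substrate
        * (_MASS["C"] + 2 * _MASS["O"])
        / 1000.0,
    }
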