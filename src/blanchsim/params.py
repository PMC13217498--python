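"""Packaged default parameter sets for green-bean blanching.

Fitted kinetic parameters for the green-bean enzymes and the pectin/texture
model, together with the heat-transfer defaults.  Reference temperatures of
the inactivation rate constants were not part of the published fits; the
values used here are package assumptions placed in the middle of the
temperature range of the underlying data and are flagged ``assumed_t_ref``
on the rate objects (see docs/methods.md).

All energies are stored in J/mol, rates in s^-1, temperatures in kelvin.
"""

from __future__ import annotations

from .kinetics import (
    ArrheniusRate,
    BiphasicInactivation,
    MonophasicInactivation,
    PectinParameters,
)
from .thermal import GREEN_BEAN, BathProgram, BathSegment, Composition, CylinderGeometry

__all__ = [
    "CELSIUS_OFFSET",
    "lox_biphasic",
    "pod_biphasic",
    "pme_monophasic",
    "texture_parameters",
    "default_geometry",
    "default_composition",
    "default_bath",
    "HEAT_TRANSFER_COEFFICIENT",
    "INITIAL_TEMPERATURE_C",
]

CELSIUS_OFFSET = 273.15

#: Film coefficient of stirred hot-water blanching baths, W m^-2 K^-1.
HEAT_TRANSFER_COEFFICIENT = 1000.0

#: Product temperature before immersion, deg C.
INITIAL_TEMPERATURE_C = 25.0


def default_composition() -> Composition:
    """Green-bean proximate composition (mass fractions)."""
    return GREEN_BEAN


def default_geometry(n_cells: int = 5) -> CylinderGeometry:
    """9 mm diameter bean pod as an infinite cylinder."""
    return CylinderGeometry(radius=4.5e-3, n_cells=n_cells)


def default_bath(bath_c: float, hold_s: float = 300.0) -> BathProgram:
    """Constant-temperature immersion starting at 25 C product temperature."""
    return BathProgram(
        INITIAL_TEMPERATURE_C,
        (BathSegment(hold_s, bath_c),),
        HEAT_TRANSFER_COEFFICIENT,
    )


def lox_biphasic() -> BiphasicInactivation:
    """Biphasic LOX inactivation fitted to isothermal green-bean extract data.

    Reported as an isoform *ratio* EnzI(0)/EnzII(0) = 0.53 with
    dE_I = 282 kJ/mol, dE_II = 96 kJ/mol, k_I,ref = 0.36e-3 s^-1,
    k_II,ref = 0.028 s^-1.  Reference temperature assumed 60 C (mid-range of
    the 55-70 C data).
    """
    t_ref = 60.0 + CELSIUS_OFFSET
    return BiphasicInactivation.from_ratio(
        0.53,
        ArrheniusRate(0.36e-3, t_ref, 282e3, assumed_t_ref=True),
        ArrheniusRate(0.028, t_ref, 96e3, assumed_t_ref=True),
    )


def pod_biphasic() -> BiphasicInactivation:
    """Biphasic POD inactivation fitted to whole-bean data.

    Isoform *fraction* EnzI(0)/(EnzI(0)+EnzII(0)) = 0.70,
    k_I,ref = 12e-5 s^-1, k_II,ref = 6.8e-4 s^-1, dE_I = 0.37 MJ/mol,
    dE_II = 4.7 MJ/mol.  Reference temperature assumed 80 C (mid-range of
    the 70-100 C data).
    """
    t_ref = 80.0 + CELSIUS_OFFSET
    return BiphasicInactivation(
        0.70,
        ArrheniusRate(12e-5, t_ref, 0.37e6, assumed_t_ref=True),
        ArrheniusRate(6.8e-4, t_ref, 4.7e6, assumed_t_ref=True),
    )


def pme_monophasic() -> MonophasicInactivation:
    """Monophasic PME inactivation fitted to whole-bean data.

    k_D,ref = 91e-3 s^-1, dE = 315 kJ/mol; reference temperature assumed
    80 C.
    """
    return MonophasicInactivation(
        ArrheniusRate(91e-3, 80.0 + CELSIUS_OFFSET, 315e3, assumed_t_ref=True)
    )


def texture_parameters() -> PectinParameters:
    """Pectin/texture parameters for whole green beans.

    beta-elimination k_beta(373 K) = 0.2e-3 s^-1 with dE = 200 kJ/mol; PME
    demethylation activity k_m(338 K) = 0.011 s^-1 with dE = 100 kJ/mol;
    PME denaturation k_d taken from the monophasic inactivation fit; initial
    degree of methylation 0.8.
    """
    return PectinParameters(
        k_beta=ArrheniusRate(0.2e-3, 373.15, 200e3),
        k_m=ArrheniusRate(0.011, 338.15, 100e3),
        k_d=pme_monophasic().rate,
        dm0=0.8,
    )
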