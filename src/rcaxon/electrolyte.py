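"""Electrolyte conductivity and lumped compartment impedance.

The artificial axon is a Plexiglas channel partitioned by copper plates into
ten electrolyte-filled wells.  Each well behaves as a parallel RC element whose
resistance is set by the bulk conductivity of the aqueous K2SO4 solution and
whose capacitance is set by the plate geometry and the dielectric constant of
water.  This module converts electrolyte composition into bulk conductivity
and, together with the channel geometry, into the per-well lumped R and C that
feed the circuit model.

Units are SI throughout: concentrations in mol/L, conductivity in S/m,
lengths in m, resistance in ohm, capacitance in farad.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "EPS0",
    "LAMBDA_K",
    "LAMBDA_SO4",
    "WATER_REL_PERMITTIVITY",
    "DEFAULT_CONDUCTION_PATH",
    "SolutionState",
    "ChannelGeometry",
    "conductivity_from_concentration",
    "compartment_impedance",
    "conductivity_from_resistance",
]

#: Vacuum permittivity, F/m.
EPS0 = 8.8541878128e-12

#: Limiting molar ionic conductivity of K+ at 25 degC, S·cm²/mol.
LAMBDA_K = 73.5
#: Limiting molar ionic conductivity of SO4²⁻ at 25 degC, S·cm²/mol.
LAMBDA_SO4 = 160.0

#: Static relative permittivity of water, valid for the MHz-scale pulse
#: circuit (the 53.37 GHz dielectric response lives in :mod:`em_dosimetry`).
WATER_REL_PERMITTIVITY = 80.0

#: Default effective conduction path from launch to termination plate, m.
#: Nine 1-cm well-to-well gaps separate the first and last plates.
DEFAULT_CONDUCTION_PATH = 0.09

#: Measured conductivity of the plain glycine/sucrose medium (0 mM K2SO4),
#: S/m; equals 0.33 uS/cm.  Not derivable from the stated composition, so it
#: is carried as a lumped background constant.
DEFAULT_BACKGROUND_CONDUCTIVITY = 3.3e-5


@dataclass(frozen=True)
class SolutionState:
    """External aqueous medium in the channel.

    Parameters
    ----------
    c_k2so4 : float
        K2SO4 concentration, mol/L.
    background_conductivity : float
        Conductivity of the solvent medium without added K2SO4, S/m.
    temperature : float
        Absolute temperature, K.
    """

    c_k2so4: float
    background_conductivity: float = DEFAULT_BACKGROUND_CONDUCTIVITY
    temperature: float = 298.15

    def __post_init__(self) -> None:
        if self.c_k2so4 < 0:
            raise ValueError(f"c_k2so4 must be >= 0, got {self.c_k2so4}")
        if self.background_conductivity < 0:
            raise ValueError("background_conductivity must be >= 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0 K")


@dataclass(frozen=True)
class ChannelGeometry:
    """Geometry of the partitioned channel.

    Defaults describe the as-built device: a 10 cm x 1 cm x 2 cm channel
    filled to 3 mm depth, with vertical copper plates every 1 cm forming ten
    wells.  The submerged plate area (channel width x solution depth) is the
    electrode area of each well capacitor.
    """

    channel_length: float = 0.10
    channel_width: float = 0.01
    solution_depth: float = 0.003
    plate_spacing: float = 0.01
    n_wells: int = 10

    def __post_init__(self) -> None:
        for name in ("channel_length", "channel_width", "solution_depth", "plate_spacing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_wells < 1:
            raise ValueError("n_wells must be >= 1")

    @property
    def plate_area_submerged(self) -> float:
        """Submerged electrode area of one plate, m²."""
        return self.channel_width * self.solution_depth


def conductivity_from_concentration(
    state: SolutionState,
    lambda_k: float = LAMBDA_K,
    lambda_so4: float = LAMBDA_SO4,
) -> float:
    """Bulk conductivity of a K2SO4 solution from limiting ionic conductivities.

    Treats the salt as fully dissociated (K2SO4 -> 2 K+ + SO4²⁻) at infinite
    dilution, so the molar conductivity is ``2*lambda_k + lambda_so4`` and

        kappa = c * (2*lambda_k + lambda_so4) + background,

    with the unit conversion 1 (S·cm²/mol)·(mol/L) = 0.1 S/m.  The result is
    affine and strictly increasing in concentration; no Kohlrausch sqrt(c)
    correction is applied.

    Parameters
    ----------
    state : SolutionState
    lambda_k, lambda_so4 : float
        Limiting molar ionic conductivities, S·cm²/mol.

    Returns
    -------
    float
        Conductivity, S/m.
    """
    if lambda_k <= 0 or lambda_so4 <= 0:
        raise ValueError("limiting molar ionic conductivities must be > 0")
    molar_conductivity = 2.0 * lambda_k + lambda_so4  # S·cm²/mol
    return state.c_k2so4 * molar_conductivity * 0.1 + state.background_conductivity


def compartment_impedance(
    geometry: ChannelGeometry,
    conductivity: float,
    rel_permittivity: float = WATER_REL_PERMITTIVITY,
) -> tuple[float, float]:
    """Lumped resistance and capacitance of one well.

    The electrolyte slab between two adjacent plates is a parallel-plate
    element:

        R = d / (kappa * A),    C = eps0 * eps_r * A / d,

    with ``d`` the plate spacing and ``A`` the submerged plate area.

    A non-conducting solution (``conductivity == 0``) returns
    ``R = math.inf`` rather than raising: an open-circuit well is a valid
    limiting configuration for the ladder.

    Returns
    -------
    (resistance, capacitance) : tuple of float
        Ohm and farad.
    """
    if conductivity < 0:
        raise ValueError("conductivity must be >= 0")
    area = geometry.plate_area_submerged
    if conductivity == 0.0:
        resistance = math.inf
    else:
        resistance = geometry.plate_spacing / (conductivity * area)
    capacitance = EPS0 * rel_permittivity * area / geometry.plate_spacing
    return resistance, capacitance


def conductivity_from_resistance(
    total_resistance: float,
    path_length: float = DEFAULT_CONDUCTION_PATH,
    cross_section: float = 3.0e-5,
) -> float:
    """Back-calculate bulk conductivity from an end-to-end resistance.

    Inverse of the series-resistance formula for a uniform conductor:
    ``sigma = L / (R * A)``.  With the device defaults (9 cm launch-to-
    termination path, 3e-5 m² submerged cross-section) an end-to-end
    resistance of 92 kOhm gives about 0.03 S/m.
    """
    if total_resistance <= 0 or path_length <= 0 or cross_section <= 0:
        raise ValueError("total_resistance, path_length and cross_section must be > 0")
    return path_length / (total_resistance * cross_section)
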