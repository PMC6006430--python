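"""Analytic plane-wave dosimetry for the 53.37 GHz exposure.

The sample is exposed from above by a conical horn at 8 cm (far field), so the
field inside the aqueous medium is modelled as a normally incident plane wave
entering a lossy dielectric half-space.  From the complex permittivity
``eps_c = eps' - j eps''`` the module derives the effective conductivity, the
in-medium wavelength and penetration depth, the exponential SAR depth profile

    SAR(z) = (1/2) (sigma/rho) |E(z)|^2,   E(z) = E0 exp(-z/delta),

and a lumped (adiabatic-bound) temperature rise.  This 1-D model replaces a
full-wave 3-D simulation of the horn and channel; absolute SAR therefore
depends on the supplied antenna gain and is meaningful at the
order-of-magnitude level, while sigma, delta and the profile shape are exact
for the stated permittivity.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "C0",
    "ETA0",
    "DielectricMedium",
    "ExposureSpec",
    "FieldProfile",
    "WATER_53GHZ",
    "effective_conductivity",
    "propagation_constants",
    "sar_profile",
    "surface_field_from_exposure",
    "temperature_rise",
    "absorbed_power_density",
]

#: Vacuum permittivity, F/m (shared with the electrolyte module's value).
EPS0 = 8.8541878128e-12
#: Speed of light in vacuum, m/s.
C0 = 299792458.0
#: Impedance of free space, ohm.
ETA0 = 1.0 / (EPS0 * C0)


@dataclass(frozen=True)
class DielectricMedium:
    """Lossy dielectric, ``eps_c = eps_real - j*eps_imag`` (eps_imag >= 0)."""

    eps_real: float
    eps_imag: float
    density: float = 1000.0

    def __post_init__(self) -> None:
        if self.eps_real <= 0:
            raise ValueError("eps_real must be > 0")
        if self.eps_imag < 0:
            raise ValueError("eps_imag must be >= 0 (positive-loss convention)")
        if self.density <= 0:
            raise ValueError("density must be > 0")

    @property
    def complex_permittivity(self) -> complex:
        return complex(self.eps_real, -self.eps_imag)


#: Aqueous glycine/sucrose medium at 53.37 GHz.
WATER_53GHZ = DielectricMedium(eps_real=11.76, eps_imag=24.0, density=1000.0)


@dataclass(frozen=True)
class ExposureSpec:
    """Millimetre-wave exposure geometry and power.

    Defaults describe the experiment: 53.37 GHz continuous wave, 39 mW
    radiated, horn 8 cm above the solution, 30 min exposure.  ``antenna_gain``
    (linear, relative to isotropic) is not printed for the horn and must be
    supplied before the incident power density can be derived; alternatively
    give ``incident_power_density`` directly.
    """

    frequency: float = 53.37e9
    radiated_power: float = 39.0e-3
    antenna_distance: float = 0.08
    antenna_gain: float | None = None
    incident_power_density: float | None = None
    exposure_duration: float = 1800.0

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("frequency must be > 0")
        if self.radiated_power < 0:
            raise ValueError("radiated_power must be >= 0")
        if self.antenna_distance <= 0:
            raise ValueError("antenna_distance must be > 0")


@dataclass(frozen=True)
class FieldProfile:
    """Electric-field magnitude and SAR on a depth grid (surface at z = 0)."""

    depths: np.ndarray
    e_magnitude: np.ndarray
    sar: np.ndarray

    def __post_init__(self) -> None:
        for name in ("depths", "e_magnitude", "sar"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.e_magnitude < 0) or np.any(self.sar < 0):
            raise ValueError("field magnitude and SAR must be non-negative")


def effective_conductivity(medium: DielectricMedium, frequency: float) -> float:
    """Effective conductivity sigma = 2*pi*f * eps0 * eps'' in S/m.

    For water at 53.37 GHz (eps'' = 24) this is about 71 S/m.
    """
    if frequency <= 0:
        raise ValueError("frequency must be > 0")
    return 2.0 * math.pi * frequency * EPS0 * medium.eps_imag


def propagation_constants(medium: DielectricMedium, frequency: float) -> tuple[float, float]:
    """In-medium wavelength and field penetration depth.

    With complex refractive index ``n = sqrt(eps_c)`` (principal root, so the
    wave decays into the half-space),

        lambda_med = lambda0 / Re(n),    delta = lambda0 / (2*pi*|Im(n)|),

    where delta is the e-folding depth of the *field amplitude* (the power
    decays as exp(-2 z / delta)).  A lossless medium returns
    ``delta = math.inf``.
    """
    if frequency <= 0:
        raise ValueError("frequency must be > 0")
    lam0 = C0 / frequency
    n = cmath.sqrt(medium.complex_permittivity)
    lam_med = lam0 / n.real
    delta = math.inf if medium.eps_imag == 0 else lam0 / (2.0 * math.pi * abs(n.imag))
    return lam_med, delta


def sar_profile(
    medium: DielectricMedium,
    frequency: float,
    surface_e: float,
    depths: np.ndarray,
) -> FieldProfile:
    """Exponential SAR depth profile for a surface field amplitude E0 (V/m).

    SAR(z) = (1/2)(sigma/rho) * E0^2 * exp(-2 z / delta).
    """
    if surface_e < 0:
        raise ValueError("surface_e must be >= 0")
    depths = np.asarray(depths, dtype=float)
    if np.any(depths < 0):
        raise ValueError("depths must be >= 0")
    sigma = effective_conductivity(medium, frequency)
    _, delta = propagation_constants(medium, frequency)
    e_mag = surface_e * np.exp(-depths / delta)
    sar = 0.5 * (sigma / medium.density) * e_mag**2
    return FieldProfile(depths=depths, e_magnitude=e_mag, sar=sar)


def surface_field_from_exposure(spec: ExposureSpec, medium: DielectricMedium) -> float:
    """Transmitted field amplitude just inside the medium surface, V/m.

    The incident power density is either supplied directly or derived from the
    far-field formula ``S = P*G / (4 pi r^2)`` (requires ``antenna_gain``).
    The incident field is ``E_inc = sqrt(2 S eta0)`` and normal-incidence
    Fresnel transmission into the half-space gives ``E0 = |2/(1+n)| * E_inc``.
    """
    if spec.incident_power_density is not None:
        s_inc = spec.incident_power_density
    else:
        if spec.antenna_gain is None:
            raise ValueError(
                "antenna_gain is required to derive the incident power density "
                "(or supply incident_power_density directly)"
            )
        s_inc = spec.radiated_power * spec.antenna_gain / (4.0 * math.pi * spec.antenna_distance**2)
    e_inc = math.sqrt(2.0 * s_inc * ETA0)
    n = cmath.sqrt(medium.complex_permittivity)
    t = 2.0 / (1.0 + n)
    return abs(t) * e_inc


def incident_power_density(spec: ExposureSpec) -> float:
    """Far-field incident power density S = P*G/(4 pi r^2), W/m²."""
    if spec.incident_power_density is not None:
        return spec.incident_power_density
    if spec.antenna_gain is None:
        raise ValueError("antenna_gain required")
    return spec.radiated_power * spec.antenna_gain / (4.0 * math.pi * spec.antenna_distance**2)


def absorbed_power_density(profile: FieldProfile, medium: DielectricMedium) -> float:
    """Absorbed power per unit surface area, W/m², by trapezoidal quadrature.

    Integrates ``SAR(z) * rho`` over the profile's depth grid; with a grid
    extending several penetration depths this approaches the transmitted
    Poynting flux.
    """
    return float(np.trapezoid(profile.sar * medium.density, profile.depths))


def temperature_rise(
    sar: float,
    duration: float,
    specific_heat: float = 4186.0,
    loss_rate: float = 0.0,
) -> float:
    """Lumped-medium temperature rise under constant SAR heating.

    Solves ``dT/dt = SAR/c_p - loss_rate * T`` from T(0) = 0:

    * ``loss_rate = 0``: adiabatic bound ``SAR * t / c_p`` — an upper bound on
      any measured rise, since every loss channel only removes heat.
    * ``loss_rate > 0``: ``(SAR/(c_p*loss_rate)) * (1 - exp(-loss_rate*t))``.
    """
    if sar < 0 or duration < 0 or specific_heat <= 0 or loss_rate < 0:
        raise ValueError("sar, duration >= 0; specific_heat > 0; loss_rate >= 0")
    if loss_rate == 0.0:
        return sar * duration / specific_heat
    return (sar / (specific_heat * loss_rate)) * (1.0 - math.exp(-loss_rate * duration))
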