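"""Light-energy conversions and reactor illumination geometry.

Irradiance (W m^-2) is what a pyranometer at the vessel surface reads;
phototrophic physiology runs on photons, so the first step of any analysis
is the conversion to a photon flux (umol photons m^-2 s^-1),

    Phi = I * lambda * 1e6 / (N_A * h * c),

with the wavelength taken either as a single value or as the midpoint of the
infrared band passed by the lamp filter. The biomass-specific light supply
rate r_EX = Phi * A / (X_av * V) then expresses how many photons each gram of
biomass receives per second — the quantity that separates light-limited from
substrate-limited operation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "PhysicalConstants",
    "ReactorGeometry",
    "LightField",
    "photon_flux",
    "band_average_photon_flux",
    "irradiated_area",
    "specific_light_supply_rate",
    "attenuated_mean_irradiance",
]


@dataclass(frozen=True)
class PhysicalConstants:
    """Fundamental constants used in the energy-to-photon conversion.

    Defaults are the physical values; all three are overridable so that
    alternative printed roundings can be reproduced exactly.
    """

    avogadro: float = 6.022e23  # photons per mole
    planck: float = 6.626e-34  # J s
    light_speed: float = 2.998e8  # m s^-1

    def __post_init__(self) -> None:
        if self.avogadro <= 0 or self.planck <= 0 or self.light_speed <= 0:
            raise ValueError("physical constants must be strictly positive")


@dataclass(frozen=True)
class ReactorGeometry:
    """Cylindrical stirred-tank photobioreactor geometry.

    Parameters
    ----------
    inner_diameter : float
        Vessel inner diameter in metres.
    working_volume : float
        Liquid working volume in litres.
    illuminated_sides : int
        Number of lamp-facing sides (1 or 2).
    transmittance : float
        Fraction of incident light passing the vessel wall, in (0, 1].
    """

    inner_diameter: float = 0.11
    working_volume: float = 2.0
    illuminated_sides: int = 2
    transmittance: float = 1.0

    def __post_init__(self) -> None:
        if self.inner_diameter <= 0:
            raise ValueError("inner_diameter must be > 0")
        if self.working_volume <= 0:
            raise ValueError("working_volume must be > 0")
        if self.illuminated_sides not in (1, 2):
            raise ValueError("illuminated_sides must be 1 or 2")
        if not 0 < self.transmittance <= 1:
            raise ValueError("transmittance must be in (0, 1]")

    @property
    def liquid_height(self) -> float:
        """Liquid column height in metres for the cylindrical vessel."""
        radius = self.inner_diameter / 2.0
        return (self.working_volume * 1e-3) / (math.pi * radius**2)


@dataclass(frozen=True)
class LightField:
    """An incident light condition: irradiance plus spectral placement."""

    incident_irradiance: float
    wavelength: float | None = None  # nm, single-wavelength conversion
    band: tuple[float, float] | None = (700.0, 1100.0)  # nm, IR-filtered supply

    def __post_init__(self) -> None:
        if self.incident_irradiance < 0:
            raise ValueError("incident_irradiance must be >= 0")
        if self.wavelength is None and self.band is None:
            raise ValueError("either wavelength or band must be given")


def photon_flux(
    irradiance: float,
    wavelength: float,
    constants: PhysicalConstants = PhysicalConstants(),
) -> float:
    """Convert irradiance to photon flux at a single wavelength.

    Parameters
    ----------
    irradiance : float
        Radiant power density in W m^-2.
    wavelength : float
        Wavelength in nm.

    Returns
    -------
    float
        Photon flux in umol photons m^-2 s^-1.
    """
    if wavelength <= 0:
        raise ValueError("wavelength must be > 0")
    if irradiance < 0:
        raise ValueError("irradiance must be >= 0")
    lam_m = wavelength * 1e-9
    return (
        irradiance
        * lam_m
        * 1e6
        / (constants.avogadro * constants.planck * constants.light_speed)
    )


def band_average_photon_flux(
    irradiance: float,
    band: tuple[float, float],
    constants: PhysicalConstants = PhysicalConstants(),
) -> float:
    """Photon flux averaged over a wavelength band.

    The per-wavelength flux is linear in lambda, so the uniform average over
    [lo, hi] equals the flux at the band midpoint.
    """
    lo, hi = band
    if lo <= 0 or hi <= 0:
        raise ValueError("band edges must be > 0")
    if lo > hi:
        raise ValueError(f"inverted band: [{lo}, {hi}]")
    return photon_flux(irradiance, (lo + hi) / 2.0, constants)


def irradiated_area(geometry: ReactorGeometry) -> float:
    """Projected illuminated area of the vessel in m^2.

    Uses the planar projection convention: each lamp-facing side contributes
    a rectangle of diameter x liquid height.
    """
    return geometry.illuminated_sides * geometry.inner_diameter * geometry.liquid_height


def specific_light_supply_rate(
    flux: float,
    area: float,
    biomass_avg: float,
    volume: float,
) -> float:
    """Biomass-specific light supply rate r_EX.

    Parameters
    ----------
    flux : float
        Photon flux in umol photons m^-2 s^-1.
    area : float
        Irradiated surface in m^2.
    biomass_avg : float
        Cycle-average biomass concentration in g VSS L^-1; must be > 0
        (dark or washed-out conditions have no meaningful r_EX and must be
        handled upstream).
    volume : float
        Working volume in L.

    Returns
    -------
    float
        r_EX in umol photons s^-1 gVSS^-1.
    """
    if biomass_avg <= 0:
        raise ValueError("biomass_avg must be > 0 for a specific supply rate")
    if flux < 0 or area <= 0 or volume <= 0:
        raise ValueError("flux must be >= 0; area and volume must be > 0")
    return flux * area / (biomass_avg * volume)


def attenuated_mean_irradiance(
    incident: float,
    biomass: float,
    specific_attenuation: float,
    path: float,
) -> float:
    """Path-averaged irradiance inside a biomass suspension.

    One-dimensional Beer–Lambert attenuation over a planar path of length
    `path` (cm) with biomass-specific attenuation coefficient
    `specific_attenuation` (L g^-1 cm^-1): the average of
    incident * exp(-k X l) over l in [0, path], i.e.
    incident * (1 - exp(-k X L)) / (k X L). Tends to `incident` as the
    optical depth goes to zero.
    """
    if incident < 0 or biomass < 0 or specific_attenuation < 0 or path < 0:
        raise ValueError("all inputs must be >= 0")
    tau = specific_attenuation * biomass * path  # optical depth, dimensionless
    if tau < 1e-12:
        return incident
    return incident * (1.0 - math.exp(-tau)) / tau
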