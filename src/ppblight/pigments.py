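"""Photopigment peak detection and Beer–Lambert quantification.

Bacteriochlorophyll a and carotenoids (lycopene as the representative
species) are quantified from absorbance wavelength scans of hexane extracts.
At a pigment's peak wavelength the Beer–Lambert law A = eps * C * D relates
absorbance to molar concentration C given the molar absorption coefficient
eps (M^-1 cm^-1) and the cuvette pathlength D (cm). The mass fraction
(mg per g of dry biomass) follows from the molar mass, the solvent volume
recovered and the biomass dry mass extracted:

    w = C * M * V_solvent * 1000 / m_biomass.

Whole-cell scans are only peak-reported (light scattering and the
protein-bound in-vivo band shifts make Beer–Lambert quantification invalid
for intact cells).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SpectralScan",
    "PigmentSpec",
    "PigmentQuantification",
    "BCHL_A",
    "LYCOPENE",
    "DEFAULT_EXTRACT_PIGMENTS",
    "find_peak",
    "quantify_concentration",
    "mass_fraction",
    "quantify_scan",
    "report_whole_cell_peaks",
]


@dataclass
class SpectralScan:
    """An absorbance wavelength scan.

    ``sample_kind`` is ``"extract"`` (quantifiable) or ``"whole_cells"``
    (peak reporting only). ``biomass_g`` and ``solvent_L`` describe the
    extraction (dry mass used, hexane-phase volume recovered) and are needed
    for mass fractions.
    """

    wavelengths: np.ndarray  # nm, strictly increasing
    absorbance: np.ndarray
    sample_kind: str = "extract"
    pathlength: float = 0.5  # cm
    biomass_g: float | None = None
    solvent_L: float | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavelengths.shape != self.absorbance.shape:
            raise ValueError("wavelength and absorbance grids differ in length")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance must be finite")
        if self.pathlength <= 0:
            raise ValueError("pathlength must be > 0")
        if self.sample_kind not in ("extract", "whole_cells"):
            raise ValueError("sample_kind must be 'extract' or 'whole_cells'")

    @property
    def has_sample_meta(self) -> bool:
        return self.biomass_g is not None and self.solvent_L is not None


@dataclass(frozen=True)
class PigmentSpec:
    """Identification and optical constants of one pigment."""

    name: str
    peak_wavelength: float  # nm
    molar_extinction: float  # M^-1 cm^-1 at the peak
    molar_mass: float  # g mol^-1
    search_window: tuple[float, float]  # nm

    def __post_init__(self) -> None:
        if self.molar_extinction <= 0:
            raise ValueError("molar_extinction must be > 0")
        lo, hi = self.search_window
        if not lo <= self.peak_wavelength <= hi:
            raise ValueError("search_window must contain peak_wavelength")


# Default pigment definitions for hexane extracts. Extinction coefficients are
# molar absorption coefficients at the extract peak; molar masses convert the
# molar concentration to a mass fraction.
BCHL_A = PigmentSpec(
    name="bacteriochlorophyll_a",
    peak_wavelength=776.0,
    molar_extinction=6.0e4,
    molar_mass=911.5,
    search_window=(740.0, 820.0),
)
LYCOPENE = PigmentSpec(
    name="lycopene",
    peak_wavelength=473.0,
    molar_extinction=1.72e5,
    molar_mass=536.87,
    search_window=(450.0, 500.0),
)
DEFAULT_EXTRACT_PIGMENTS = (BCHL_A, LYCOPENE)

# Whole-cell reporting windows (in-vivo bands are red-shifted and
# protein-dependent; no quantification is attempted there)
WHOLE_CELL_BCHL_WINDOW = (780.0, 920.0)
WHOLE_CELL_CAROTENOID_WINDOW = (300.0, 550.0)


@dataclass(frozen=True)
class PigmentQuantification:
    """Result of quantifying one pigment in one extract scan."""

    pigment: str
    peak_found: float | None  # nm; None when no peak was detected
    absorbance_at_peak: float | None
    molar_concentration: float | None  # M
    mass_fraction: float | None  # mg gVSS^-1; None without sample meta

    @property
    def detected(self) -> bool:
        return self.peak_found is not None


def _linear_baseline(wl: np.ndarray, ab: np.ndarray) -> np.ndarray:
    """Straight line through the window endpoints."""
    return ab[0] + (ab[-1] - ab[0]) * (wl - wl[0]) / (wl[-1] - wl[0])


def find_peak(
    scan: SpectralScan,
    window: tuple[float, float],
    baseline: str = "none",
) -> tuple[float, float] | None:
    """Locate the maximum of the (optionally baseline-corrected) absorbance.

    Returns ``(wavelength_nm, absorbance)`` of the in-window maximum, with
    ties broken toward the lowest wavelength, or ``None`` when the window
    contains no interior local maximum above the baseline (a monotone ramp or
    a flat/blank signal is not a peak).
    """
    lo, hi = window
    mask = (scan.wavelengths >= lo) & (scan.wavelengths <= hi)
    if mask.sum() < 3:
        raise ValueError("window must contain at least 3 grid points")
    wl = scan.wavelengths[mask]
    ab = scan.absorbance[mask].copy()
    if baseline == "linear-endpoints":
        ab = ab - _linear_baseline(wl, ab)
    elif baseline != "none":
        raise ValueError("baseline must be 'none' or 'linear-endpoints'")

    idx = int(np.argmax(ab))  # argmax takes the first (lowest-wavelength) tie
    # An endpoint maximum means the true peak lies outside the window (or the
    # signal is monotone): not a detection.
    if idx == 0 or idx == len(ab) - 1:
        return None
    if ab[idx] <= 0 and baseline == "linear-endpoints":
        return None
    # require a genuine interior rise above both neighbours' minimum level
    if ab[idx] <= ab[0] and ab[idx] <= ab[-1]:
        return None
    return float(wl[idx]), float(ab[idx])


def quantify_concentration(
    absorbance: float, molar_extinction: float, pathlength: float
) -> float:
    """Molar concentration from Beer–Lambert: C = A / (eps * D)."""
    if molar_extinction <= 0 or pathlength <= 0:
        raise ValueError("molar_extinction and pathlength must be > 0")
    if absorbance < 0:
        logger.warning(
            "negative absorbance %.4g after baseline subtraction; clipped to 0",
            absorbance,
        )
        absorbance = 0.0
    return absorbance / (molar_extinction * pathlength)


def mass_fraction(
    concentration: float,
    molar_mass: float,
    solvent_volume: float,
    biomass_mass: float,
) -> float:
    """Pigment mass per dry biomass, mg gVSS^-1."""
    if biomass_mass <= 0:
        raise ValueError("biomass_mass must be > 0")
    if molar_mass <= 0 or solvent_volume <= 0:
        raise ValueError("molar_mass and solvent_volume must be > 0")
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    return concentration * molar_mass * solvent_volume * 1000.0 / biomass_mass


def _local_mean_height(
    scan: SpectralScan,
    peak_nm: float,
    window: tuple[float, float],
    baseline: str,
    half_width: int = 2,
) -> float:
    """Peak absorbance as the mean of the grid points around the located peak.

    Averaging ``2*half_width + 1`` points suppresses the upward bias of
    reading a single noisy grid point at the argmax; the peak location
    itself stays on the raw grid.
    """
    lo, hi = window
    mask = (scan.wavelengths >= lo) & (scan.wavelengths <= hi)
    wl = scan.wavelengths[mask]
    ab = scan.absorbance[mask].copy()
    if baseline == "linear-endpoints":
        ab = ab - _linear_baseline(wl, ab)
    i = int(np.argmin(np.abs(wl - peak_nm)))
    sl = slice(max(0, i - half_width), min(len(ab), i + half_width + 1))
    return float(ab[sl].mean())


def quantify_scan(
    scan: SpectralScan,
    pigments: tuple[PigmentSpec, ...] = DEFAULT_EXTRACT_PIGMENTS,
    baseline: str = "none",
) -> list[PigmentQuantification]:
    """Quantify each pigment in an extract scan.

    For each pigment: find the peak in its search window, read the peak
    height as a 5-point local average around the located maximum, convert it
    to a molar concentration, and — when the scan carries extraction
    metadata — to a biomass mass fraction. Pigments without a detectable
    peak are returned flagged (``peak_found is None``) rather than dropped.

    Baseline correction is off by default: a straight line through the
    search-window endpoints removes instrument drift but sits on the
    shoulders of neighbouring bands wherever pigments absorb near the window
    edges (the carotenoid triplet especially), systematically under-reading
    the peak. Enable ``baseline="linear-endpoints"`` only for scans with
    genuine baseline drift and windows whose edges are band-free.
    """
    if scan.sample_kind != "extract":
        raise ValueError(
            "only extract scans can be quantified; whole-cell scans are "
            "peak-reported with report_whole_cell_peaks()"
        )
    out: list[PigmentQuantification] = []
    for pig in pigments:
        peak = find_peak(scan, pig.search_window, baseline=baseline)
        if peak is None:
            # no detectable band: concentration 0, flagged via peak_found=None
            frac = 0.0 if scan.has_sample_meta else None
            out.append(PigmentQuantification(pig.name, None, None, 0.0, frac))
            continue
        peak_nm, _ = peak
        peak_ab = _local_mean_height(scan, peak_nm, pig.search_window, baseline)
        conc = quantify_concentration(peak_ab, pig.molar_extinction, scan.pathlength)
        frac = None
        if scan.has_sample_meta:
            frac = mass_fraction(conc, pig.molar_mass, scan.solvent_L, scan.biomass_g)
        out.append(PigmentQuantification(pig.name, peak_nm, peak_ab, conc, frac))
    return out


def report_whole_cell_peaks(
    scan: SpectralScan,
    windows: dict[str, tuple[float, float]] | None = None,
    prominence_fraction: float = 0.05,
) -> pd.DataFrame:
    """List local absorbance maxima of a whole-cell scan per spectral region.

    Reports every interior local maximum whose prominence over its
    surroundings exceeds ``prominence_fraction`` of the window's dynamic
    range. Used to read the in-vivo bacteriochlorophyll band structure
    (e.g. 800/890 nm under light-saturating growth versus 805/866 nm under
    light limitation) without attempting quantification.
    """
    from scipy.signal import find_peaks

    if windows is None:
        windows = {
            "bchl_in_vivo": WHOLE_CELL_BCHL_WINDOW,
            "carotenoid": WHOLE_CELL_CAROTENOID_WINDOW,
        }
    rows = []
    for region, (lo, hi) in windows.items():
        mask = (scan.wavelengths >= lo) & (scan.wavelengths <= hi)
        wl = scan.wavelengths[mask]
        ab = scan.absorbance[mask]
        if len(wl) < 3:
            continue
        span = float(ab.max() - ab.min())
        prom = prominence_fraction * span if span > 0 else None
        if prom is None:
            continue
        idx, _ = find_peaks(ab, prominence=prom)
        for i in idx:
            rows.append(
                {
                    "region": region,
                    "peak_nm": float(wl[i]),
                    "absorbance": float(ab[i]),
                }
            )
    return pd.DataFrame(rows, columns=["region", "peak_nm", "absorbance"])
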