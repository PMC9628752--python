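"""Synthetic data with the statistical structure of an infrared-lit,
acetate-fed sequencing-batch photobioreactor study.

Every generator here is seeded and deterministic, and writes/returns the
same objects the analysis modules consume, so the full pipeline can run
without any external data. The simulator integrates dual light/substrate
limitation,

    dX/dt = mu(x(t)) * S/(Ks + S) * X - k_d * X,
    dS/dt = -mu(x(t)) * S/(Ks + S) * X / Y,

with mu(.) the logistic light response and x(t) either the (constant)
incident irradiance or the biomass-dependent specific light supply rate
r_EX (self-shading). Cycles are chained with SRT-controlled purging of
mixed liquor, ideal settling, and a 50% volume exchange of supernatant for
fresh feed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .kinetics import CycleSeries, logistic
from .light import (
    PhysicalConstants,
    ReactorGeometry,
    band_average_photon_flux,
    irradiated_area,
    specific_light_supply_rate,
)
from .pigments import BCHL_A, LYCOPENE, SpectralScan
from .proteomics import ProteinAbundanceTable

__all__ = [
    "SBRConfig",
    "LightModelParams",
    "KineticParams",
    "NoiseModel",
    "PigmentResponse",
    "SimulationResult",
    "PAPER_IRRADIANCES",
    "simulate_cycle",
    "simulate_condition",
    "generate_growth_rate_dataset",
    "generate_spectrum",
    "generate_whole_cell_spectrum",
    "generate_protein_table",
    "generate_community_series",
    "child_seeds",
]

# The nine incident-irradiance conditions of the study design, W m^-2
PAPER_IRRADIANCES = (350.0, 264.0, 175.0, 87.0, 30.0, 15.0, 7.0, 3.0, 0.0)


def child_seeds(seed: int, n: int) -> list[int]:
    """Deterministically fan one master seed out to n child seeds (< 2^31)."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


@dataclass(frozen=True)
class SBRConfig:
    """Sequencing-batch-reactor operating schedule.

    Durations in minutes; the cycle length is their sum (510 min with the
    defaults). The purge removes mixed liquor so that the solids retention
    time equals ``srt``: purge fraction per cycle = cycle_length / srt.
    """

    feed_min: float = 5.0
    react_min: float = 281.0
    purge_min: float = 4.0
    settle_min: float = 210.0
    discharge_min: float = 5.0
    idle_min: float = 5.0
    exchange_ratio: float = 0.5
    srt_h: float = 31.0
    feed_acetate: float = 6.7  # mmol L^-1
    settling_efficiency: float = 1.0  # fraction of biomass retained at discharge
    geometry: ReactorGeometry = field(default_factory=ReactorGeometry)

    def __post_init__(self) -> None:
        for name in ("feed_min", "react_min", "purge_min", "settle_min",
                     "discharge_min", "idle_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.exchange_ratio < 1:
            raise ValueError("exchange_ratio must be in (0, 1)")
        if self.srt_h < self.cycle_length_h:
            raise ValueError("srt must be >= cycle length")
        if not 0 <= self.settling_efficiency <= 1:
            raise ValueError("settling_efficiency must be in [0, 1]")

    @property
    def cycle_length_h(self) -> float:
        total_min = (
            self.feed_min + self.react_min + self.purge_min
            + self.settle_min + self.discharge_min + self.idle_min
        )
        return total_min / 60.0

    @property
    def purge_fraction(self) -> float:
        return self.cycle_length_h / self.srt_h


@dataclass(frozen=True)
class LightModelParams:
    """Ground-truth logistic light response used by the simulator."""

    a: float = 0.25  # h^-1
    b: float = 0.025  # per x-unit
    c: float = 189.0  # x-units
    x_kind: str = "incident_W_m2"

    def mu(self, x) -> np.ndarray:
        return logistic(x, self.a, self.b, self.c)


# rEX-axis variant: half-saturation at 34 umol s^-1 gVSS^-1; steepness scaled
# so the response covers the same dynamic range over the smaller axis.
REX_LIGHT_MODEL = LightModelParams(a=0.25, b=0.025 * 189.0 / 34.0, c=34.0,
                                   x_kind="rEX_umol_s_gVSS")


@dataclass(frozen=True)
class KineticParams:
    """Kinetic constants of the simulated phototrophic enrichment."""

    light_model: LightModelParams = field(default_factory=LightModelParams)
    Ks_acetate: float = 0.05  # mmol L^-1
    yield_gVSS_per_mmol: float = 0.045
    decay: float = 0.0  # h^-1
    limitation: str = "multiplicative"  # or "minimum"
    wavelength_band: tuple[float, float] = (700.0, 1100.0)

    def __post_init__(self) -> None:
        if self.Ks_acetate <= 0 or self.yield_gVSS_per_mmol <= 0:
            raise ValueError("Ks and yield must be > 0")
        if self.decay < 0:
            raise ValueError("decay must be >= 0")
        if self.limitation not in ("multiplicative", "minimum"):
            raise ValueError("limitation must be 'multiplicative' or 'minimum'")

    @property
    def mu_max(self) -> float:
        return self.light_model.a


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal observation noise."""

    observation_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.observation_cv < 0:
            raise ValueError("cv must be >= 0")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.observation_cv == 0:
            return np.asarray(values, dtype=float)
        sigma = math.sqrt(math.log(1.0 + self.observation_cv**2))
        factors = rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma,
                                size=np.shape(values))
        return np.asarray(values, dtype=float) * factors


@dataclass(frozen=True)
class PigmentResponse:
    """Pigment mass fraction as a declining saturation function of irradiance:
    w(I) = w_min + (w_max - w_min) * K_w / (K_w + I)."""

    w_max: float = 3.8  # mg gVSS^-1 in the dark / low light
    w_min: float = 0.8  # mg gVSS^-1 under saturating light
    K_w: float = 50.0  # W m^-2

    def __post_init__(self) -> None:
        if not self.w_max > self.w_min > 0:
            raise ValueError("requires w_max > w_min > 0")
        if self.K_w <= 0:
            raise ValueError("K_w must be > 0")

    def mass_fraction(self, irradiance: float) -> float:
        return self.w_min + (self.w_max - self.w_min) * self.K_w / (
            self.K_w + irradiance
        )


def _growth_rate(
    X: float, S: float, irradiance: float, params: KineticParams, config: SBRConfig
) -> float:
    """Instantaneous specific growth rate under dual limitation."""
    lm = params.light_model
    if lm.x_kind == "incident_W_m2":
        x = irradiance
    else:  # rEX: recompute from current biomass (self-shading)
        if X <= 0 or irradiance <= 0:
            return -params.decay
        flux = band_average_photon_flux(irradiance, params.wavelength_band)
        area = irradiated_area(config.geometry)
        x = specific_light_supply_rate(
            flux, area, X, config.geometry.working_volume
        )
    mu_light = float(lm.mu(x))
    monod = S / (params.Ks_acetate + S) if S > 0 else 0.0
    if params.limitation == "multiplicative":
        mu = mu_light * monod
    else:
        mu = min(mu_light, params.mu_max * monod)
    return mu - params.decay


def simulate_cycle(
    config: SBRConfig,
    params: KineticParams,
    X0: float,
    S0: float,
    irradiance: float,
    dt_min: float = 1.0,
    cycle_id: str = "cycle",
) -> CycleSeries:
    """Integrate one reaction phase with fixed-step fourth-order Runge–Kutta.

    Returns the noiseless trajectory sampled at every integration step
    (time in hours from the start of the reaction phase).
    """
    if dt_min <= 0:
        raise ValueError("dt must be > 0")
    if X0 < 0 or S0 < 0:
        raise ValueError("X0 and S0 must be >= 0")
    if X0 == 0 and irradiance > 0:
        raise ValueError("X0 must be > 0 under illumination")

    T = config.react_min / 60.0
    n = max(1, int(round(config.react_min / dt_min)))
    dt = T / n
    t = np.empty(n + 1)
    X = np.empty(n + 1)
    S = np.empty(n + 1)
    t[0], X[0], S[0] = 0.0, X0, S0

    def deriv(Xi: float, Si: float) -> tuple[float, float]:
        Si = max(Si, 0.0)
        mu = _growth_rate(Xi, Si, irradiance, params, config)
        growth = mu + params.decay  # substrate is consumed by gross growth
        dX = mu * Xi
        dS = -growth * Xi / params.yield_gVSS_per_mmol if Si > 0 else 0.0
        return dX, dS

    for i in range(n):
        Xi, Si = X[i], S[i]
        k1x, k1s = deriv(Xi, Si)
        k2x, k2s = deriv(Xi + dt / 2 * k1x, Si + dt / 2 * k1s)
        k3x, k3s = deriv(Xi + dt / 2 * k2x, Si + dt / 2 * k2s)
        k4x, k4s = deriv(Xi + dt * k3x, Si + dt * k3s)
        X[i + 1] = Xi + dt / 6 * (k1x + 2 * k2x + 2 * k3x + k4x)
        S[i + 1] = max(Si + dt / 6 * (k1s + 2 * k2s + 2 * k3s + k4s), 0.0)
        t[i + 1] = t[i] + dt

    return CycleSeries(
        condition_irradiance=irradiance,
        cycle_id=cycle_id,
        time=t,
        biomass=X,
        acetate=S,
    )


@dataclass
class SimulationResult:
    """Outcome of a multi-cycle condition simulation."""

    cycles: list[CycleSeries]  # last k cycles, observation noise applied
    converged: bool
    n_cycles_run: int
    steady_biomass: float  # end-of-cycle biomass of the final cycle (noiseless)
    steady_acetate: float  # end-of-reaction acetate of the final cycle


def simulate_condition(
    config: SBRConfig,
    params: KineticParams,
    irradiance: float,
    n_cycles: int = 60,
    noise: NoiseModel | None = None,
    X0: float = 0.7,
    keep_last: int = 3,
    rel_tol: float = 0.01,
    dt_min: float = 1.0,
    sample_every_min: float = 15.0,
) -> SimulationResult:
    """Chain SBR cycles to (cyclic) steady state at one irradiance.

    After each reaction phase the purge removes ``purge_fraction`` of the
    biomass, settling retains the rest (times ``settling_efficiency``),
    half the volume is discharged as supernatant and replaced with feed
    (acetate mixes to (1-ratio)*S_end + ratio*feed). Convergence is declared
    when the end-of-cycle biomass changes by less than ``rel_tol`` between
    consecutive cycles; washing-out conditions never converge and are
    returned flagged with the last cycles anyway.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    noise = noise or NoiseModel(observation_cv=0.0)
    rng = np.random.default_rng(noise.seed)

    ratio = config.exchange_ratio
    f = config.purge_fraction
    X = X0
    S = (1 - ratio) * 0.0 + ratio * config.feed_acetate  # first fill
    retained = (1 - f) * (
        config.settling_efficiency + (1 - config.settling_efficiency) * (1 - ratio)
    )

    kept: list[CycleSeries] = []
    converged = False
    prev_end = None
    n_run = 0
    last = None
    for i in range(n_cycles):
        cyc = simulate_cycle(
            config, params, X, S, irradiance, dt_min=dt_min, cycle_id=f"c{i+1:03d}"
        )
        n_run += 1
        last = cyc
        X_end = float(cyc.biomass[-1])
        S_end = float(cyc.acetate[-1])
        kept.append(cyc)
        if len(kept) > keep_last:
            kept.pop(0)
        if prev_end is not None and prev_end > 0:
            if abs(X_end - prev_end) / prev_end < rel_tol:
                converged = True
                break
        prev_end = X_end
        X = X_end * retained
        S = (1 - ratio) * S_end + ratio * config.feed_acetate

    # thin to the sampling grid and apply observation noise last
    stride = max(1, int(round(sample_every_min / dt_min)))
    observed = []
    for cyc in kept:
        idx = np.arange(0, len(cyc.time), stride)
        if idx[-1] != len(cyc.time) - 1:
            idx = np.append(idx, len(cyc.time) - 1)
        observed.append(
            CycleSeries(
                condition_irradiance=cyc.condition_irradiance,
                cycle_id=cyc.cycle_id,
                time=cyc.time[idx],
                biomass=noise.apply(cyc.biomass[idx], rng),
                acetate=noise.apply(cyc.acetate[idx], rng),
            )
        )
    return SimulationResult(
        cycles=observed,
        converged=converged,
        n_cycles_run=n_run,
        steady_biomass=float(last.biomass[-1]),
        steady_acetate=float(last.acetate[-1]),
    )


def generate_growth_rate_dataset(
    true_model: LightModelParams,
    x_levels,
    replicates: int = 3,
    noise_sigma: float = 0.01,
    seed: int = 0,
) -> pd.DataFrame:
    """Growth rates from a known logistic plus Gaussian noise.

    Returns a DataFrame with columns ``x`` (light level) and ``mu_h``;
    ``replicates`` rows per light level, reproducible from ``seed``.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    x = np.repeat(np.asarray(x_levels, dtype=float), replicates)
    mu = true_model.mu(x) + rng.normal(0.0, noise_sigma, size=len(x))
    return pd.DataFrame({"x": x, "mu_h": mu})


# Gaussian band templates for extract spectra: (centre nm, sigma nm, relative
# height). The quantified peak of each pigment carries relative height 1.
EXTRACT_TEMPLATES = {
    BCHL_A.name: [(776.0, 12.0, 1.0), (389.0, 10.0, 0.45)],
    LYCOPENE.name: [(446.0, 10.0, 0.8), (473.0, 10.0, 1.0), (511.0, 10.0, 0.6)],
}

WHOLE_CELL_TEMPLATES = {
    # in-vivo band positions shift with the light-harvesting stoichiometry
    "high_light": [(800.0, 15.0, 1.0), (890.0, 18.0, 0.9),
                   (322.0, 12.0, 0.5), (370.0, 12.0, 0.45)],
    "low_light": [(805.0, 15.0, 1.0), (866.0, 18.0, 0.95),
                  (322.0, 12.0, 0.5), (370.0, 12.0, 0.45)],
}

_PIGMENT_SPECS = {BCHL_A.name: BCHL_A, LYCOPENE.name: LYCOPENE}


def generate_spectrum(
    mass_fractions: dict[str, float],
    biomass_g: float = 0.005,
    solvent_L: float = 6.0e-4,
    pathlength: float = 0.5,
    noise_cv: float = 0.01,
    seed: int = 0,
    grid: tuple[float, float, float] = (320.0, 1100.0, 1.0),
) -> SpectralScan:
    """Synthesise an extract absorbance scan from known pigment mass fractions.

    Peak heights invert the Beer–Lambert relation: a requested mass fraction
    w (mg gVSS^-1) with extraction metadata (biomass_g, solvent_L) implies a
    molar concentration C = w * biomass_g / (molar_mass * solvent_L * 1000)
    and a peak absorbance A = eps * C * pathlength. Additive Gaussian noise
    with sd = noise_cv * tallest peak.
    """
    lo, hi, step = grid
    wl = np.arange(lo, hi + step / 2, step)
    ab = np.zeros_like(wl)
    max_height = 0.0
    for name, w in mass_fractions.items():
        if w < 0:
            raise ValueError("mass fractions must be >= 0")
        spec = _PIGMENT_SPECS[name]
        conc = w * biomass_g / (spec.molar_mass * solvent_L * 1000.0)
        peak_a = conc * spec.molar_extinction * pathlength
        max_height = max(max_height, peak_a)
        for centre, sigma, rel in EXTRACT_TEMPLATES[name]:
            ab += peak_a * rel * np.exp(-((wl - centre) ** 2) / (2 * sigma**2))
    if noise_cv > 0 and max_height > 0:
        rng = np.random.default_rng(seed)
        ab = ab + rng.normal(0.0, noise_cv * max_height, size=len(wl))
    return SpectralScan(
        wavelengths=wl,
        absorbance=ab,
        sample_kind="extract",
        pathlength=pathlength,
        biomass_g=biomass_g,
        solvent_L=solvent_L,
    )


def generate_whole_cell_spectrum(
    light_regime: str = "high_light",
    amplitude: float = 0.8,
    noise_cv: float = 0.01,
    seed: int = 0,
    grid: tuple[float, float, float] = (320.0, 1100.0, 1.0),
) -> SpectralScan:
    """Whole-cell scan with the in-vivo band structure of a light regime."""
    if light_regime not in WHOLE_CELL_TEMPLATES:
        raise ValueError(f"light_regime must be one of {list(WHOLE_CELL_TEMPLATES)}")
    lo, hi, step = grid
    wl = np.arange(lo, hi + step / 2, step)
    ab = np.zeros_like(wl)
    for centre, sigma, rel in WHOLE_CELL_TEMPLATES[light_regime]:
        ab += amplitude * rel * np.exp(-((wl - centre) ** 2) / (2 * sigma**2))
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        ab = ab + rng.normal(0.0, noise_cv * amplitude, size=len(wl))
    return SpectralScan(wavelengths=wl, absorbance=ab, sample_kind="whole_cells")


def generate_protein_table(
    n_proteins: int = 1000,
    conditions=(350, 87, 15),
    reference=87,
    category_effects: dict[str, dict] | None = None,
    category_sizes: dict[str, int] | None = None,
    taxa: list[str] | None = None,
    n_replicates: int = 3,
    lognormal_sigma: float = 0.2,
    seed: int = 0,
) -> ProteinAbundanceTable:
    """Replicate protein peak-area table with injected category effects.

    Baseline protein abundances are lognormal; for proteins in a category
    with an effect, the mean in a non-reference condition is multiplied by
    2**log2fc; replicate noise is lognormal with sd ``lognormal_sigma`` on
    the log scale. ``category_effects`` maps category -> {condition: log2fc};
    proteins not assigned to a category carry no effect ("background").
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2 for testing")
    if reference not in conditions:
        raise ValueError("reference must be among conditions")
    rng = np.random.default_rng(seed)
    category_effects = category_effects or {}
    category_sizes = category_sizes or {}

    proteins = [f"P{i:05d}" for i in range(n_proteins)]
    cats = np.array(["background"] * n_proteins, dtype=object)
    pos = 0
    for cat in category_effects:
        size = category_sizes.get(cat, max(1, n_proteins // 20))
        if pos + size > n_proteins:
            raise ValueError("category sizes exceed n_proteins")
        cats[pos : pos + size] = cat
        pos += size

    baseline = rng.lognormal(mean=0.0, sigma=1.0, size=n_proteins)
    samples, areas, cond_labels = [], [], []
    for cond in conditions:
        shift = np.ones(n_proteins)
        for cat, effects in category_effects.items():
            fc = effects.get(cond, 0.0)
            if cond != reference and fc != 0.0:
                shift[cats == cat] = 2.0**fc
        for rep in range(1, n_replicates + 1):
            noise_f = rng.lognormal(mean=0.0, sigma=lognormal_sigma, size=n_proteins) \
                if lognormal_sigma > 0 else np.ones(n_proteins)
            areas.append(baseline * shift * noise_f)
            samples.append(f"{cond}_r{rep}")
            cond_labels.append(cond)

    area_df = pd.DataFrame(
        np.column_stack(areas), index=proteins, columns=samples
    )
    conditions_s = pd.Series(cond_labels, index=samples, name="condition")
    taxa_s = None
    if taxa:
        taxa_s = pd.Series(rng.choice(taxa, size=n_proteins), index=proteins)
    cats_s = pd.Series(cats, index=proteins)
    return ProteinAbundanceTable(
        areas=area_df, conditions=conditions_s, taxa=taxa_s, categories=cats_s
    )


def generate_community_series(
    taxa: dict[str, LightModelParams],
    config: SBRConfig,
    irradiances=PAPER_IRRADIANCES,
    n_srt: float = 8.0,
    X0_each: float = 0.1,
) -> pd.DataFrame:
    """Relative taxon abundances after competition under shared purging.

    Each taxon grows exponentially during the reaction phase at its own
    light-limited rate and is purged with the common purge fraction; taxa
    whose realised growth per cycle falls below the purge loss wash out.
    Returns relative abundances per (irradiance, cycle), plus the final
    composition marker column ``final``.
    """
    if not taxa:
        raise ValueError("at least one taxon required")
    n_cycles = max(1, int(math.ceil(n_srt * config.srt_h / config.cycle_length_h)))
    T = config.react_min / 60.0
    f = config.purge_fraction
    rows = []
    for irr in irradiances:
        X = {name: X0_each for name in taxa}
        for cyc in range(1, n_cycles + 1):
            for name, lm in taxa.items():
                mu = float(lm.mu(irr)) if irr > 0 else 0.0
                X[name] = X[name] * math.exp(mu * T) * (1 - f)
            total = sum(X.values())
            for name in taxa:
                rows.append(
                    {
                        "irradiance_W_m2": irr,
                        "cycle": cyc,
                        "taxon": name,
                        "relative_abundance": X[name] / total if total > 0 else np.nan,
                        "final": cyc == n_cycles,
                    }
                )
    return pd.DataFrame(rows)
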