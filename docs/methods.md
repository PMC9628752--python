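# Methods

This note documents the models, conventions, default parameters and
numerical choices behind `ppblight`, and what the synthetic-data tests do
and do not demonstrate about real reactor data.

## Light energy and reactor geometry

Irradiance I (W m⁻²) converts to photon flux Φ (μmol photons m⁻² s⁻¹) via
Φ = I·λ·10⁶/(N_A·h·c). Constants default to the physical values
(N_A = 6.022×10²³, h = 6.626×10⁻³⁴ J s, c = 2.998×10⁸ m s⁻¹) and are
overridable so alternative printed roundings can be reproduced exactly.
Because Φ is linear in λ, the average over a uniform wavelength band equals
the flux at the band midpoint; the default band is the infrared-filtered
700–1100 nm supply (midpoint 900 nm), and a single-wavelength path is
exposed because the conversion wavelength is a modelling choice that must
stay visible (940 nm reproduces the familiar 1.4 W m⁻² → 11 μmol m⁻² s⁻¹
low-light conversion).

The illuminated area of the cylindrical vessel uses the projected-rectangle
convention: A = (number of lamp-facing sides) × (inner diameter) × (liquid
height), with liquid height V/(π r²). For the default two-sided, 11-cm,
2.0-L geometry this gives A = 0.0463 m². Vessel transmittance defaults to
1.0 and, when set, scales the incident irradiance before conversion.

The specific light supply rate r_EX = Φ·A/(X_av·V) uses the cycle-average
biomass convention X_av = (1 − exchange_ratio/2)·X_end: a 50% volume
exchange starts each cycle at half its end concentration, and the average
is the midpoint. Under this convention the 87 W m⁻² reference condition
(X_end = 2.04 g L⁻¹) sits at r_EX ≈ 9.4–10.3 μmol photons s⁻¹ gVSS⁻¹
across conversion wavelengths 850–940 nm — the regime boundary. r_EX is
undefined without a standing population; conditions with biomass below
0.01 g L⁻¹ (washout) are reported as NaN rather than as huge per-gram
supplies.

A Beer–Lambert helper gives the path-averaged irradiance inside a
suspension, I·(1−e^(−kXL))/(kXL); it is a one-dimensional planar
approximation with no scattering or refraction.

## Growth-rate estimation

μ = ln(X₁/X₀)/(T₁−T₀) between window endpoints, or the slope of ln X
against time over the window; both agree exactly on clean exponential data.
Estimation windows matter in an SBR because substrate depletion flattens
the trajectory partway through the reaction phase. Three window policies
are provided:

- **full phase** (endpoint or regression) — the plain convention; it
  understates the light-set rate whenever acetate runs out mid-phase;
- **substrate window** (default in the pipeline) — log-linear slope over
  the observations collected while acetate remains above 5% of its initial
  value. Growth is substrate-unlimited there, so the slope estimates the
  light-set rate. Falls back to the full phase when acetate never depletes
  or no acetate data exist;
- **R²-screened window** — longest early window whose log-linear fit
  reaches R² ≥ 0.98. Usable without substrate data, but on noisy
  low-dynamic-range series (observation CV 5%, log-biomass span ≲ 0.3) no
  window can pass the screen and short windows that pass by chance carry
  large slope errors; the substrate window is preferred whenever acetate
  was measured.

Biomass observations ≤ 0 are rejected, not clipped.

## Logistic light-response fit

μ(x) = a/(1+exp(−b(x−c))) is fitted by unweighted nonlinear least squares
(trust-region reflective, via `scipy.optimize.curve_fit`). Initialisation:
a₀ = max(y), b₀ = 4/range(x), c₀ multi-started at 5 equispaced points in
[min(x), max(x)]. Bounds: a ∈ (0, 2·max(y)], b > 0, c ∈ [min(x), max(x)].
Parameter standard errors come from the asymptotic covariance. The fit is
permutation-invariant and scale-consistent (rescaling x by s rescales c by
s and b by 1/s, leaving a unchanged).

Flat or uninformative data collapse onto the b → 0 ridge, where the
prediction is the constant a/2 and the asymptote is not separately
identified (with c bounded inside the data range no parameter choice can
put every observation on the plateau, so the ridge optimum is genuinely
the least-squares solution). Such fits are returned with
``degenerate=True`` and an exploding/inestimable steepness error rather
than silently.

On the bundled nine-condition summary the incident-light fit gives
a = 0.240 ± 0.020 h⁻¹ and c = 198 ± 17 W m⁻²; on the r_EX axis the
half-saturation falls to the tens because the per-gram supply axis is
compressed by the standing biomass.

## Regimes and washout

A condition is **dark** at zero irradiance; otherwise **acetate-limited**
when residual acetate is at or below the detection limit (default
0.02 mmol L⁻¹) or r_EX ≥ 10 μmol photons s⁻¹ gVSS⁻¹, else
**light-limited**. Both thresholds are configurable.

The washout growth rate is 1/SRT (0.032 h⁻¹ at 31 h). This is the
continuous, first-order rule: in the discrete cycle balance, a culture is
stationary at μ = −ln(1−f)/T_react with f the per-cycle purge fraction,
which is larger because growth happens only during the reaction phase. The
package reports 1/SRT (the conventional process-design number) and the
simulator realises the discrete balance; the distinction is why simulated
low-light cultures wash out even at growth rates slightly above 1/SRT.

## Pigment spectra

Extract scans are quantified at the pigment peak via A = ε·C·D with
defaults ε = 6×10⁴ M⁻¹ cm⁻¹ at 776 nm (bacteriochlorophyll *a*, molar mass
911.5 g mol⁻¹), ε = 1.72×10⁵ M⁻¹ cm⁻¹ at 473 nm (lycopene, 536.87 g
mol⁻¹), D = 0.5 cm; mass fraction = C·M·V_solvent·1000/m_biomass
(mg gVSS⁻¹). The extinction coefficients are treated as molar absorption
coefficients in M⁻¹ cm⁻¹ — the magnitudes match literature molar values —
with the molar→mass conversion done explicitly through the molar masses;
all four constants are overridable.

Peaks are located as the in-window maximum on the raw 1-nm grid (ties to
the lowest wavelength; endpoint maxima are "not found", distinguishing a
monotone ramp from a band). The peak *height* is read as the mean of the 5
grid points centred on the located maximum, which suppresses the upward
bias of reading a single noisy point. Linear endpoint-baseline correction
is available but off by default for quantification: the carotenoid search
window [450, 500] nm has the 446- and 511-nm components of the lycopene
triplet sitting on its edges, so an endpoint baseline swallows roughly half
the 473-nm peak; enable it only for windows whose edges are band-free.
Negative heights after correction are clipped to zero with a logged
warning. Whole-cell scans are peak-reported only (in-vivo 800/890 nm bands
under light-saturating growth, 805/866 nm under light limitation);
scattering and the protein-bound band shifts make Beer–Lambert
quantification invalid for intact cells.

## Differential metaproteomics

Peak areas are normalised per sample to percent of total (columns sum to
exactly 100). Each condition is compared to a fixed reference condition
protein-by-protein: Welch's two-sided t-test on replicate percentages
(Student's pooled-variance variant available), log₂ fold change of
condition means with a pseudocount (default: half the smallest nonzero
normalised value, applied inside the ratio only, logged). Calls use strict
thresholds p < 0.05 and |log₂FC| > 0.5; boundary values are not
significant. No multiple-testing correction is applied by default;
Benjamini–Hochberg is available behind a flag. Groups with (numerically)
zero variance and equal means give p = 1 by convention.

Category/taxon aggregation reports per-group mean percentages, mean ± sd of
log₂ fold changes and up/down/ns counts; unannotated proteins fall into
"unclassified".

**Compositional closure.** Percent normalisation makes abundances sum to
100, so boosting one category deflates every other: a category holding a
fraction s of total signal, boosted 2^fc-fold, is recovered at
fc − log₂(1 + (2^fc−1)·s) and background proteins acquire an apparent
−log₂(1+(2^fc−1)·s). Recovery of injected effects is therefore only exact
for small categories; calibration experiments keep the perturbed category
at ≲2% of total signal. This is a property of the percent scale itself,
not of the implementation, and applies equally to real data. Calibration
of the null is checked with the pooled-variance test because the
generator's replicate groups are exactly homoscedastic (Welch's
small-sample conservativeness would otherwise be conflated with
miscalibration); Welch remains the analysis default for real data.

## Synthetic SBR generator

The simulator integrates, with fixed-step fourth-order Runge–Kutta
(dt = 1 min) over the 281-min reaction phase,

    dX/dt = μ X − k_d X,   dS/dt = −(μ + k_d)·X/Y (gross growth),
    μ = μ_light(x) · S/(K_S + S),

with μ_light the logistic response (defaults a = 0.25 h⁻¹, b = 0.025 per
W m⁻², c = 189 W m⁻² on the incident axis; c = 34 with b rescaled on the
r_EX axis, where x is recomputed each step from current biomass —
self-shading). Dual limitation is multiplicative by default (a min()
variant is available). Defaults: K_S = 0.05 mmol L⁻¹, yield
Y = 0.045 g VSS per mmol acetate (≈0.9 Cmol Cmol⁻¹), decay 0, feed acetate
6.7 mmol L⁻¹ (sodium acetate trihydrate at 0.914 g L⁻¹).

Cycles chain as: react → purge (fraction = cycle length/SRT of the mixed
liquor; 510 min/31 h ≈ 0.27 with the printed phase durations) → ideal
settling (configurable efficiency) → 50% volume exchange (acetate mixes to
(1−r)·S_end + r·feed) → refill. Convergence is declared when end-of-cycle
biomass changes < 1% between cycles; washing-out conditions never converge
and are returned flagged. Observations are thinned to a 15-min sampling
grid — fine enough to resolve the ~70-min high-light depletion transient
that the cycle data are meant to exhibit — and multiplicative lognormal
noise (CV 5%) is applied last.

Under the default mass balance the fully-depleting conditions settle near
0.55 g VSS L⁻¹ — the qualitative structure (acetate depletion above
~175 W m⁻², residual acetate and washout below ~30 W m⁻², biomass
non-decreasing in irradiance) matches the reference study, but absolute
concentrations in the g L⁻¹ range would require a feed several-fold
stronger than the printed recipe supports; the generator makes no attempt
to force them. Pigment mass fractions follow
w(I) = w_min + (w_max−w_min)·K_w/(K_w+I) (w_max = 3.8, w_min = 0.8
mg gVSS⁻¹, K_w = 50 W m⁻²); extract spectra are sums of Gaussian bands
(bacteriochlorophyll 776 nm σ = 12 nm; lycopene 446/473/511 nm σ = 10 nm,
height ratios 0.8/1.0/0.6) with heights inverted from the requested mass
fraction through the Beer–Lambert constants. Protein tables are lognormal
baselines with per-category fold-change shifts and lognormal replicate
noise (σ = 0.2). All generators are seeded; one master seed fans out to
stage seeds via `numpy.random.SeedSequence`.

### What the synthetic tests do and do not show

The generators share their functional forms with the analysis models
(logistic response, Beer–Lambert bands, lognormal noise), so round-trip
and recovery tests demonstrate correctness of the estimation machinery —
not that real PPB cultures follow a logistic, that extract baselines are
flat, or that peak-area noise is lognormal. Real data add scattering
baselines, overlapping bands beyond the modelled triplet, biofilm and
settling non-idealities, community composition shifts between conditions,
and missing-at-random proteins — none of which the generator emulates.

## Problem sizes

Defaults keep every stage desk-scale: nine conditions × ≤60 cycles × 1-min
integration steps for the simulator; 200-seed parameter-recovery
benchmarks at 27 observations per fit; 1000-protein tables with
triplicates; 50-seed pigment round trips. The entire suite runs in about a
minute on one core.

## Known limitations

- No photoinhibition term: the logistic saturates and never declines, so
  the model extrapolates poorly beyond the calibrated irradiance range.
- The r_EX-axis fit depends on per-condition average biomass; with washout
  conditions excluded it rests on few points and is reported as a
  consistency check rather than a primary estimate.
- Peak detection is argmax-based; strongly overlapping or shifted bands
  need spectral unmixing, which is out of scope.
- The t-test stage inherits the reference procedure's choices (no
  multiple-testing correction by default, percent-scale testing); both are
  switchable but the defaults mirror common practice in the field's
  peak-area workflows.
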