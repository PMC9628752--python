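# ppblight

Growth kinetics, light-energy budgets, photopigment quantification and
differential metaproteomics for **purple phototrophic bacteria (PPB)**
cultivated in infrared-lit sequencing batch photobioreactors (SBRs).

PPB are anoxygenic photoorganoheterotrophs of interest for wastewater
resource recovery: they grow on acetate with near-unity biomass yields,
powered by infrared light harvested with bacteriochlorophyll/carotenoid
complexes. The central design question for such processes is how much light
a culture needs: below a threshold photon supply growth is *light-limited*
(residual substrate is left at the end of a reactor cycle), above it the
culture turns *substrate-limited* and runs at its maximum rate. `ppblight`
provides the quantitative toolkit for analysing that transition, for users
running or modelling mixed-culture PPB photobioreactors.

## The model

Specific growth rates μ (h⁻¹), computed within an SBR reaction phase as
μ = ln(X₁/X₀)/(T₁−T₀), respond to the light supply *x* through a generic
logistic,

    μ(x) = a / (1 + exp(−b (x − c))),

with *a* the asymptotic maximum growth rate μ_max, *c* a half-saturation
constant for light K_L, and *b* a steepness factor. The light axis is either
the incident irradiance I (W m⁻²) or the biomass-specific photon supply rate

    r_EX = Φ · A / (X_av · V)    [μmol photons s⁻¹ gVSS⁻¹],

where Φ = I·λ·10⁶/(N_A·h·c) converts irradiance to photon flux at
wavelength λ, A is the illuminated reactor area and X_av the cycle-average
biomass. Supporting stages cover Beer–Lambert pigment quantification
(A = ε·C·D at the extract peak, 776 nm for bacteriochlorophyll *a*, 473 nm
for lycopene), limitation-regime classification (r_EX ≈ 10 μmol s⁻¹ gVSS⁻¹
boundary), the SRT washout threshold μ_min = 1/SRT, and percent-normalised
protein fold-change/t-test statistics. A seeded synthetic-data module
simulates the full SBR (dual light/substrate limitation, purging, volume
exchange) so every stage runs without external data.

## Worked example

```python
from ppblight import LightResponseModel
from ppblight.datasets import load_condition_means

tbl = load_condition_means()       # nine irradiance conditions, 0-350 W/m2
res = LightResponseModel(tbl["irradiance_W_m2"], tbl["mu_h"]).fit()
print(res.summary())
```

```
Logistic light-response fit: mu(x) = a / (1 + exp(-b (x - c)))
x kind: incident_W_m2   n obs: 9
converged: True   degenerate: False
residual sum of squares: 0.000724197
----------------------------------------------------------
parameter                   estimate       std err
----------------------------------------------------------
a (mu_max, h^-1)             0.23998       0.01967
b (per incident_W_m2)       0.016237      0.002419
c (K_L, incident_W_m2)        198.31         17.07
----------------------------------------------------------
```

The asymptote says the enrichment tops out near μ_max ≈ 0.24 h⁻¹; the
half-saturation c ≈ 198 W m⁻² marks the incident irradiance at which growth
runs at half that rate. With the reactor's 31-h solids retention time,
`washout_rate(31.0)` gives 0.0323 h⁻¹ — populations growing slower than
this are purged faster than they divide.

The same objects drive the command line:

```
ppblight fit-kinetics              # fit + regime calls on the bundled summary
ppblight full --seed 1 --out run/  # simulate -> fit -> classify -> report
ppblight reproduce-targets         # headline quantities, computed fresh
```

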