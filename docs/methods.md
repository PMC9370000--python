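# Methods

## Scope and structure

`photonox` computes steady-state concentrations of photochemically produced
reactive intermediates (PPRIs) in a well-mixed, sunlit water column, with the
nitrogen dioxide radical and its dimer as the focal species, and apportions
the indirect phototransformation of a dissolved probe compound among the
reactive pathways. Everything is a closed-form steady state; there is no
transient mode and no randomness.

Pipeline: `spectra` (photon field) → `ppri` (•OH/CO₃•⁻/³CDOM*/¹O₂/Br₂•⁻
budget) → `nox` (•NO₂/N₂O₄) → `probes` (apportionment), orchestrated by
`runner`/`cli`.

## Photon field

The incident spectrum is a clear-sky surface UV spectrum on a 1 nm grid over
290–400 nm, generated from a documented parameterization — an
extraterrestrial irradiance baseline (12 anchor points, linearly
interpolated) attenuated by an ozone Huggins-band term (cross-section
1.5×10⁻¹⁸ cm² at 290 nm decaying with a 6.6 nm e-folding length, 300 DU
column), molecular (Rayleigh) scattering, and a moderate aerosol term
(τ = 0.15 at 400 nm, Ångström exponent 1.3), all at airmass 1.2. Only the
*shape* matters: the table is always rescaled so its 290–400 nm integral
equals the requested UV irradiance (default 22 W m⁻², a fair-weather
mid-July mid-latitude value). Users can substitute any measured spectrum
from CSV; it is resampled onto the native grid.

Photon absorption uses single-beam Lambert–Beer competition. At each
wavelength the column of depth d absorbs the fraction 1 − 10^(−a_tot·d) of
the incident photon flux; each absorber takes the share a_i/a_tot of that.
Volumetric rates (einstein L⁻¹ s⁻¹) follow by trapezoid integration over
wavelength, division by depth (in cm) and the 1000 cm³ L⁻¹ conversion. The
per-species rates partition the total exactly — this identity is enforced in
tests to 10⁻¹⁰. No scattering, surface reflection or diurnal integration:
one irradiance snapshot, vertical beam (path geometry factor 1).

Absorbers:

* **Nitrate**: Gaussian band fit, peak 302 nm, ε = 7.2 M⁻¹ cm⁻¹, 1/e
  half-width 20 nm.
* **Nitrite**: Gaussian band fit, peak 354 nm, ε = 22.7 M⁻¹ cm⁻¹, 1/e
  half-width 26 nm.
* **CDOM**: a(λ) = 0.45 · DOC · e^(−0.015(λ−450)) m⁻¹ — the standard
  exponential-slope parameterization, linear in DOC (mg_C L⁻¹).

## Reactive-intermediate budget

Every species obeys concentration = (total source)/(total first-order sink),
except Br₂•⁻ whose dimerization adds a quadratic term (positive root of
2k_dim x² + Lx = rate, evaluated in cancellation-free form).

**•OH sources** (M s⁻¹): nitrate photolysis Φ_NO3 × cage × absorbed photons
(Φ_NO3 = 0.015; this same rate is the •NO₂ photolysis source, 1:1
stoichiometry); nitrite photolysis (Φ = 0.025); CDOM photochemistry
(apparent yield 5×10⁻⁶ per absorbed photon). The solvent-cage factor
1 + Δ·c_IC/(c_half + c_IC) (Δ = 1, c_half = 1 mM on total inorganic carbon)
models the enhancement of nitrate photolysis by HCO₃⁻/CO₃²⁻, which inhibit
in-cage geminate recombination of the photofragments; it saturates at 2×.

**•OH sinks** (s⁻¹): k·c for DOM (5×10⁴ L mg_C⁻¹ s⁻¹, the upper end of the
accepted (2–5)×10⁴ range), HCO₃⁻ (8.5×10⁶), CO₃²⁻ (3.9×10⁸), Br⁻
(1.1×10¹⁰) and NO₂⁻ (10¹⁰ M⁻¹ s⁻¹).

**CO₃•⁻**: formed by •OH + HCO₃⁻/CO₃²⁻ and by ³CDOM* + CO₃²⁻ (10⁵ M⁻¹ s⁻¹,
literature order); sunk by DOM (10² L mg_C⁻¹ s⁻¹). Its oxidation of nitrite
is *not* fed into •NO₂ formation — that channel is insignificant.

**³CDOM\*/¹O₂**: triplet formation = Φ_ISC × CDOM-absorbed photons
(Φ_ISC = 0.01) over a total loss constant of 10⁶ s⁻¹ (O₂ quenching plus
internal decay); ¹O₂ = half of the triplet decays transfer to O₂, over the
2.5×10⁵ s⁻¹ solvent-collision loss. At DOC = 1, 5 m, 22 W m⁻² both pools sit
at 1.3–2.7×10⁻¹⁶ M.

**Br₂•⁻**: •OH + Br⁻ gives Br•, converted quantitatively to Br₂•⁻ in excess
bromide (a warning is logged below 10⁻⁵ M Br⁻, where that assumption is
marginal). Formation rate = total •OH formation × bromide share of the
scavenging capacity. Sinks: DOM (3×10² L mg_C⁻¹ s⁻¹), nitrite
(2×10⁷ M⁻¹ s⁻¹), dimerization (1.8×10⁹ M⁻¹ s⁻¹).

## •NO₂ / N₂O₄

Sources: nitrate photolysis and k₂[•OH][NO₂⁻] (baseline, always on);
optionally k(Br₂•⁻+NO₂⁻)[Br₂•⁻][NO₂⁻] and the *upper-limit* triplet channel
k ≤ 10⁹ M⁻¹ s⁻¹ × [³CDOM*][NO₂⁻], both off by default and labelled
accordingly in outputs.

The exact steady state solves R = a x² + bx (a = 2k₃k₅/(k₋₃+k₅)
≈ 1.14×10⁸ M⁻¹ s⁻¹, b = k₄·DOC) via x = 2R/(b + √(b² + 4aR)) — the
formulation that does not cancel when the DOM sink dominates, which is
precisely the realistic regime. It remains valid at DOC = 0 (pure
dimerization/hydrolysis sink); the linear form R/(k₄·DOC) refuses DOC = 0.
The reported per-mille deviation 1000(simplified − exact)/exact is ≥ 0 by
construction and grows with R. An independent ODE-relaxation oracle
(stiff Radau integration of the two-species rate equations from zero initial
conditions, with analytic Jacobian and derivative-norm convergence checks)
verifies the closed form to 10⁻⁶ relative on a log grid spanning
R ∈ [10⁻¹⁶, 10⁻⁹] M s⁻¹ and DOC ∈ [0.1, 20].

## Probe apportionment

Each pathway contributes k_2nd × [species] to the probe's pseudo-first-order
loss; fractions are normalized, and the half-life is ln 2 over the total.
Glutathione defaults: •OH 3.5×10⁹, ³CDOM* 8×10⁷, Br₂•⁻ 2×10⁸, •NO₂ 10⁷
M⁻¹ s⁻¹ (the last is an order-of-magnitude estimate, overridable); GSH has
no direct-photolysis channel and no CO₃•⁻/¹O₂ constants, though the probe
interface accepts them for other compounds. When every concentration is zero
the fractions are flagged undefined rather than returned as 0/0.

## Calibration of the photochemical core

The absolute photon scale and the quantum-yield set were calibrated, once,
against two anchors internal to the model's problem setting: (i) the
³CDOM*/¹O₂ pools at DOC 1, 5 m, 22 W m⁻² should sit near 10⁻¹⁶ M, and
(ii) at 11 µM nitrate and DOC 1 the two baseline •NO₂ sources should
contribute equally near 0.85 µM nitrite (equivalently, nitrite oxidation
overtakes photolysis below a nitrate:nitrite ratio of order 10). All
calibrated values (Φ_NO3 = 0.015, Φ_NO2 = 0.025, Φ_OH,CDOM = 5×10⁻⁶,
k(•OH+DOM) = 5×10⁴, Φ_ISC/k_loss = 10⁻⁸ M per (einstein L⁻¹ s⁻¹), airmass
1.2, aerosol τ₄₀₀ = 0.15) lie inside their accepted literature ranges, and
every one is overridable from the config `constants` block.

## Scenario studies and presets

Presets encode the canonical study conditions (freshwater base: 5 m, 1 mM
HCO₃⁻, 10 µM CO₃²⁻, DOC 1, 22 W m⁻²; the 11 µM/0.85 µM equal-contribution
case; seawater 0.8 mM Br⁻; a brackish Rhône-delta lagoon with 50 µM nitrate,
DOC 4.5, 0.4 mM Br⁻; a flooded rice field with DOC 12). Grid sweeps are
log-spaced by default (the interesting ranges span decades), evaluated in
deterministic outer×inner order, with run metadata (constants, sweep
definition, package version) written alongside the CSV. User-facing units
are µM (nitrate, nitrite, carbonate), mM (bicarbonate, bromide), mg_C L⁻¹
(DOC); everything is SI-molar internally.

The lagoon preset's nitrite (1% of nitrate) and bromide (half-seawater,
0.4 mM) are not anchored values — they are representative choices for a
brackish, denitrifying system, made once and documented here.

## Numerical choices and degenerate inputs

* Trapezoid quadrature on the native 1 nm grid; halving the step changes
  integrated rates by < 0.1% (tested).
* All quadratic steady states use the 2R/(b+√(b²+4aR)) root form.
* Zero total sink with nonzero source raises a `DegenerateScenarioError`
  naming the missing sink; zero source with zero sink returns 0.
* The crossover search uses Brent root-finding on log₁₀(R_phot/R_OH) with
  the full pipeline re-evaluated per trial (nitrite both screens light and
  scavenges •OH), converged to |log-ratio| < 10⁻⁶.
* Grid sizes in tests and the acceptance script (7×7×5 scenario grid, 5×5
  oracle grid, 100 randomized identity checks) were chosen as the smallest
  grids that exercise every regime boundary; the whole suite runs in
  seconds.

## What the model does and does not represent

The synthetic scenarios are idealized: a single well-mixed column, one
irradiance snapshot, no pH speciation (HCO₃⁻/CO₃²⁻ are direct inputs), no
Fe(III) chemistry, no scattering, and CDOM treated as a single absorber with
a fixed spectral slope. Passing tests demonstrate internal consistency
(steady-state identities, partition identities, oracle agreement) and
agreement with the calibration anchors — not predictive accuracy for any
specific water body, which would require site-specific spectra, quantum
yields and DOM reactivity.

Known limitations worth flagging:

* With the adopted rate constants, the •NO₂ pathway dominates glutathione
  loss even in fresh water (k_NO₂[•NO₂] exceeds the •OH and ³CDOM* pathway
  constants by ~10³), so the probe apportionment is sensitive mainly to
  [•NO₂]; orderings in which •OH/³CDOM* dominate GSH loss are not
  reproduced by any parameterization consistent with the calibration
  anchors.
* The upper-limit ³CDOM* source adds a fixed ~10⁻¹³ M s⁻¹ (per µM nitrite)
  to R_NO2; relative to the baseline rate this is a ≥20% effect at DOC ≥ 1,
  growing with DOC — "upper limit" should be read literally.
* Below 10⁻⁵ M bromide the quantitative Br• → Br₂•⁻ assumption weakens;
  whether Br• has competing fates (e.g. with DOM) is not represented.
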