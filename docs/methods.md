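# Methods

## Model

`leadheat` predicts relative RF-induced lead-tip heating of an insulated,
capped wire from the transfer-function-weighted line integral of the
incident electric field,

    V = ∫₀ᵈ h(l) E(l)·dl,    ΔT = s·|V|²,

with arc length l measured from the exposed lead tip (l = 0) to the capped
IPG end (l = d). The integral is evaluated as a discrete sum over polyline
edges with the midpoint rule: h at each edge's arc-length midpoint, E at
its geometric midpoint, both multiplied by the edge vector. The midpoint
rule converges O(step²) for smooth integrands; at the 1 mm default step,
halving the step changes |V| by well under 0.1%.

Assumptions inherited from the transfer-function picture: the wire is a
uniform insulated transmission structure end to end (the exposed tip and
the cap are boundary conditions, not geometry); the incident field is
undisturbed by the wire; heating is proportional to |V|² with a single
unknown scale s conflating SAR-to-temperature physics. The package
predicts *relative* heating only.

## Wavenumbers and sign conventions

Time dependence is e^{+iωt}; travelling waves go as e^{−ikl}, so lossy
wavenumbers carry Im k ≤ 0 and |h| decays along the wire.

* Lossy medium: Re and Im magnitudes
  ω√(εμ/2)·[√(1+(σ/εω)²) ± 1]^{1/2}; returned as a non-negative pair, with
  the caller forming k_t = Re − i·Im.
* Insulator (σ = 0): k_i = ω√(ε_i μ₀), real.
* King wavenumber: k = k_i(1 + F(k_t b)/ln(b/a))^{1/2},
  F(z) = H₀(z)/(z·H₁(z)). Under the e^{+iωt} convention the outgoing
  cylindrical waves are Hankel functions of the *second* kind, which is
  what the implementation uses together with Im(k_t) ≤ 0; the square-root
  branch is flipped if needed so Im k ≤ 0. (The same numbers arise from
  first-kind Hankel functions under the opposite time convention,
  conjugated.) The ratio F is cross-checked in the tests against an
  independent ascending-series evaluation of J₀, J₁, Y₀, Y₁.
* Guided wavelength: 2π/Re(k). The real part alone sets the phase
  oscillation; including |k| would mix in attenuation.

Default physical constants: ε₀ = 8.8541878128e−12 F/m, μ₀ = 4π×10⁻⁷ H/m,
f = 63.87 MHz (1.5 T proton Larmor). The reference bench parameters
(ASTM-phantom gel σ = 0.47 S/m, ε_r = 80; insulation ε_i = 2.3,
a = 0.390 mm, b = 0.625 mm) give k_t = 14.4974 − 8.1746i rad/m,
k_i = 2.0301 rad/m, k = 6.7454 − 0.6840i rad/m, λ = 93.1 cm. The insulator
permittivity 2.3 is typical of silicone/fluoropolymer jackets and is the
value consistent with that k_i at this frequency.

## Transfer functions

* unity: h = 1 (long-wavelength limit; no k dependence).
* SEM: h(l) = e^{−ikl} — a single decaying wave.
* TLM: h(l) = e^{−ikl}(1 − Γe^{−2ik(d−l)})/(1 − Γe^{−2ikd}) — adds the
  reflection from the IPG end at l = d. Γ is a single real value in
  [0, 1): a passive termination cannot reflect more than it receives, and
  a real coefficient suffices to fit bench data; a complex Γ is
  deliberately out of scope. TLM with Γ = 0 is identically the SEM, and
  all models satisfy h(0) = 1.

## Wire geometry

Wires are declared as ordered segments from tip to IPG end: straight runs
(length + unit direction) and loop groups (integer turns, diameter,
winding sense, side-offset sign). A loop group is realized as a circle in
the coronal plane (y = 0) tangent to the direction of travel at its entry
point, displaced to one side, traversed for N full turns, and closed back
at the entry point — so it adds N·π·D of arc length and zero net
displacement, which is exactly why equal-height looped and straight wires
share the same extent. Multi-turn groups are coincident circles (zero
pitch), consistent with the coplanar bench layouts. Winding sense flips
the traversal direction (and hence the sign of the enclosed-flux term);
the side-offset sign mirrors the circle to the other side of the run.

Discretization: straight runs are subdivided to the requested `max_step`
(default 1 mm); loops get `max(160, ceil(πD/max_step))` edges per turn.
The 160-edge floor keeps the inscribed-polygon arc-length error,
≈ (π/n)²/6, below 10⁻⁴ for every loop size, and the chord length never
exceeds `max_step`.

The built-in 20-wire fixture set reproduces the bench configurations:
fifteen vertical (S/I) wires centered on isocenter at x = −10 cm — the
bench places wires off-midline where |Ez| is large, but prints no
coordinate, so one documented offset is used for all — and five horizontal
(R/L) midline wires. Loop positions "top/middle/bottom" sit at 1/4, 1/2
and 3/4 of the straight run from the tip. Two interpretations are recorded
as such rather than asserted: "back" = opposite side offset, "flipped" =
opposite winding sense. Horizontal variants are built with the same
tangent-loop construction (straight remainder = total length − N·π·D, loop
group at the run midpoint), which reproduces every quoted total length;
their quoted extents depend on figure-level layout details (where along
the run the loop sits, whether the wire folds) and are therefore carried
as metadata, not asserted geometry.

## Field models

The analytic source assumes a spatially uniform RF magnetic field
B = −b1·ŷ at ω, giving E = (0, 0, −iωb1x) — the unique linear field (up to
gauge) satisfying ∇×E = −iωB. It captures the structure that drives the
loop phenomenology in a torso phantom: Ez dominant and growing with
lateral distance from isocenter, Ex ≈ 0 on the midline. It does **not**
reproduce edge enhancement near phantom walls or any Ey structure, so
predictions here are trend-level stand-ins for full-wave field maps; the
`GriddedField` reader (HDF5 layout `/grid/{x,y,z}`,
`/field/{Ex,Ey,Ez}/{re,im}`, trilinear interpolation, exact at nodes and
for linear fields) accepts such maps when available. Default b1 = 1 µT:
predictions are relative and the fitted scale absorbs amplitude.

## Fitting and model comparison

* Scale (unity/SEM, K = 1 free parameter): closed-form least squares
  s = Σ(ΔT·|V|²)/Σ(|V|⁴).
* TLM (K = 2): Γ on a 0.001 grid over [0, 1) followed by bounded
  golden-section refinement to 10⁻⁴ between the best grid point's
  neighbours, with the closed-form scale inside; deterministic given
  inputs. The per-wire field weights (E·t̂)Δl are precomputed once per
  wire set (`WireSetDesign`), so the Γ sweep only re-evaluates h.
* RMSE = √(RSS/n); AIC = n·ln(RSS/n) + 2(K+1) (OLS form, +1 for the error
  variance). Unweighted least squares throughout: measurement errors are
  carried for reporting, not as weights.
* Bland–Altman: mean difference (model − measured) ± 1.96 sample SD
  (n − 1 denominator).

## Synthetic measurements

`synthesize_measurements` emulates a bench heating run: ΔT = s·|V|² + ε
with ε iid Normal(0, σ_noise), clipped at 0 °C, seeded. Gaussian additive
noise mirrors a quadrature-combined aggregate of probe spread,
transmit-gain fluctuation and baseline drift; it does not model
heteroscedasticity, probe placement bias or thermal-diffusion dynamics, so
recovery tests demonstrate estimator correctness under the declared noise
model, not robustness to real measurement pathologies. Under this model,
with noise at 5% of the maximum ΔT across the 20-wire set, the information
content of a single run bounds the precision of Γ̂ at roughly ±0.05 (one
s.d.); the grid+golden estimator attains that bound in Monte-Carlo
replicates.

## Numerical choices and degenerate inputs

* Midpoint quadrature (h at arc-length midpoints); endpoints would be
  first-order only.
* Loop entry/exit vertices are snapped identical so closed groups add
  exactly zero displacement despite rounding.
* b/a = 1 (ln divide-by-zero), zero-length directions, out-of-range Γ or
  arc lengths, out-of-bounds grid samples (error names the offending
  coordinate) and all-zero |V|² fits raise `ValueError` with specifics;
  `loop_vs_straight_ratio` raises `ZeroDivisionError` when the straight
  term vanishes (the midline-horizontal regime where loops dominate
  unconditionally).
* The exact 1/N turn-scaling check compares polygons with a common
  per-turn edge count so the discretization factor cancels; at mixed
  counts the law holds to ~10⁻³.

## Known limitations

Circular coplanar loops only (no helices, bends, or out-of-plane routes);
uniform insulation end to end (no IPG load, no exposed-tip geometry);
single frequency per run, no tissue dispersion; relative heating only —
absolute temperature requires a fitted scale from measurements; the
analytic field is a deliberately simple stand-in, so agreement with it
validates the machinery and the loop phenomenology, not any specific
scanner's field distribution.

## Test-suite problem sizes

Tests and the acceptance script run the full 20-wire set at the 1 mm
default step (≈400–700 edges per wire), 100-replicate Monte-Carlo for
recovery coverage, and small (≤41³) grids for interpolation round-trips —
sizes chosen so the whole suite completes in well under a minute while
keeping discretization error an order of magnitude below every asserted
tolerance.
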