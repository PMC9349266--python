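# Methods

## The transport model

The model idealizes an implanted drug reservoir in 2D with three domains: the
reservoir, the fibrous capsule (FC) wrapped around its exposed faces, and an
outer fluid rectangle standing in for the surrounding tissue space.  The
capsule is the only transport barrier represented — the device's porous
membrane (pores ~10 μm) is orders of magnitude more permeable than the
capsule and is treated as non-limiting, and no pore-scale features are
resolved.

Geometry is a cell-centred Cartesian grid (origin lower-left, y increasing
away from the device; 0-based indices, half-open intervals).  The reservoir
is a rectangle abutting the bottom boundary; the capsule is a shell of
uniform chessboard (L∞) distance from the reservoir so its cell thickness is
identical on flat faces and corners.  The reservoir's 2D outline is not
constrained by any measurement, so its extent is configurable (default
6 × 1 mm under a 5 × 20 mm outer domain).  All configuration accepts the
conventional mixed units (μm²/s, psi, mol/mm³) and converts to SI on load;
1 psi = 6894.757 Pa exactly.

### Flow (porous_flow)

Actuation drives fluid through the capsule.  We solve a single-domain
penalized Stokes–Brinkman problem on a MAC staggered grid (pressures at cell
centres, velocities on faces — this suppresses checkerboard pressure modes):

    (mu/eps) lap(u) - (mu/k) u - grad(p) = 0,   div(u) = 0

with (k, eps) = (8.9e-16 m², 0.8) in capsule cells and a penalization
permeability k_free = 1e-6 m² with eps = 1 elsewhere.  At these scales the
Darcy drag dominates the viscous term everywhere (mu/k_free ≈ 890 s·Pa/m²
vs viscous ~90 at 100 μm resolution), so the penalized formulation
reproduces the Darcy limit in the capsule to well under 1% while avoiding
explicit interface conditions.  Boundary conditions: Dirichlet inlet
pressure (the actuation amplitude) as a ghost pressure on the bottom
boundary under the reservoir footprint, zero pressure on the outer
boundaries, no-slip on solid walls.  A `side_walls` option closes the
lateral boundaries for 1D column verification against the analytic Darcy
profile.

The sparse system is solved by direct LU with iterative refinement; the
refinement recovers componentwise residuals below 1e-10 despite the wide
coefficient range of the drag terms (the refinement loop is the numerically
load-bearing detail — a single LU solve of this system is only accurate to
~1e-8).  Discrete incompressibility holds to ~1e-12 × max face speed.

Flow is quasi-static: the problem is linear, so the field is solved once at
the pulse amplitude and scaled by the instantaneous triangular waveform
(linear ramp up and down, default 2 psi over 1 s, cycles at 1 Hz).  Inertia
is neglected (Re ≪ 1 at 0.1 mm/s and 100 μm scales).

The "peri-membrane velocity" is the mean speed over the first tissue-side
cell layer adjacent to the capsule, evaluated at the waveform peak.  Where
exactly such a velocity should be probed is not defined to better than the
cell layer, so this quantity is treated as order-of-magnitude: the desk
geometry gives ~0.13 mm/s at the 2 psi peak, a factor ~2 above the 0.06 mm/s
reference scale and well inside the factor-3 band we consider meaningful.

### Concentration (drug_transport)

Drug transport obeys dc/dt = div(D grad c) - u·grad c with D piecewise
(855 μm²/s free, 50 μm²/s capsule; harmonic-mean face values), initial
concentration c0 = 1 mol/mm³ in the reservoir and zero elsewhere.  The
scheme is explicit and operator-split: conservative central-difference
diffusion plus first-order upwind advection, the latter active only while a
pulse is running.  The step is chosen at 0.4× the explicit stability limit
(diffusion and advection CFL combined); a user-supplied larger step is
reduced with a warning.  Verified properties: exact mass conservation with
closed boundaries (≤ 1e-6 relative), second-order convergence against the
2D Gaussian kernel (relative L2 ≤ 0.05% at 15 μm spacing), and positivity
(min c ≥ −1e-12 c0).

The far outer boundary default is a perfect sink (ghost concentration zero
at half-cell distance), mimicking systemic clearance of drug that has
escaped the capsule; a no-flux alternative is switchable for conservation
tests.  The bottom boundary (device wall) is always impermeable.

Release accounting: `released_fraction` is the fraction of the initial dose
no longer inside the reservoir region; `outside_fc_amount` is drug beyond
the capsule's outer face **including** what the sink has absorbed, so both
series are monotone.  "Outside the FC" means all outer-domain cells; a
narrower accounting band is a configuration choice, not a default.

### Péclet numbers

Pe = uL/D with L = 1 mm (the deflection length scale) and D = 855 μm²/s.
Interstitial flow at the top of its reported range (2 μm/s) gives
Pe = 2.339 — we report full precision; the commonly quoted 2.35 is a
rounding of the same quantity — and the ~0.06 mm/s actuated peri-membrane
flow gives Pe = 70.18.  Passive delivery is therefore diffusion-dominated
and actuated rapid release convection-dominated.

## ITT metrics (itt_analysis)

Blood-glucose series are normalized to percent of the t = 0 baseline.
Metrics: maximum % drop below baseline; time to a 30% drop with linear
interpolation between the sampling times (0, 15, …, 120 min) and censoring
at 120 min for non-responders; trapezoidal AUC of the **percent** curve over
0–120 min (the percent base matches how such data are plotted; absolute-unit
AUC is deliberately not the default).  Cumulative incidence is the empirical
fraction of animals with an event by time t; censored animals never
contribute events.  Group comparisons are pooled two-sample t-tests
(one-tailed by default for BG metrics, direction recorded in the report),
preceded by Levene's variance check, at the Bonferroni threshold α/m.
Groups with zero variance at very small n are flagged and skipped rather
than tested.

## Quantification estimators (capsule_quant)

* **Stereology** — a square point grid (pitch in μm; 100 μm pitch gives the
  classic 10,000 μm² cell) with a uniform random offset; points use the
  pixel-membership rule.  The offset is uniform over the full image extent
  with toroidal wrap, which fixes the point count and makes the estimator
  exactly unbiased for the pixel area fraction (an offset restricted to one
  pitch leaves the last partial row of pixels unsampled and biases blob
  masks detectably).
* **Vessel density** — unbiased counting frames with the Gundersen
  convention: forbidden lines on the left and bottom edges, acceptance on
  top and right.  Default estimator: total counted / (n_frames × frame
  area).  The published product form C_N × C_pts × A is exposed in a
  labelled "verbatim" mode for traceability only; it is dimensionally not a
  density and is never used in analyses.
* **Relative marker volume** — the published formula (fraction / thickness
  × 1 mm²) is the "verbatim" default; the alternative reading (fraction ×
  thickness × 1 mm²) implied by its prose description is exposed as mode
  `"prose"`.  The discrepancy is surfaced, not silently corrected.
* **Coherency** — structure tensor with Gaussian weight (σ = 2 px default),
  averaged over the ROI; coherency = (λ₁−λ₂)/(λ₁+λ₂), defined as 0 for flat
  images (gradient energy at roundoff scale).  Reflective padding is used —
  zero padding would fabricate border gradients and a spurious coherency
  floor.
* **Wall thickness** — 2D analogue of a µCT wall-thickness analysis.  The
  midline is the distance-transform ridge along the band's principal axis;
  local thickness is the mask chord through each midline point along the
  local midline normal (tangents from ±5 ridge neighbours, 0.25 px
  marching).  The chord definition is preferred over twice the inscribed
  radius because the latter dips near thickness steps.  Positions within
  one maximal inscribed radius of the band ends are trimmed.  Programmed
  bands of 5–200 px are recovered to ≤ 1 px, invariant to rotation and
  midline waviness.
* **Radiodensity** — mean over sample rectangles minus mean over background
  rectangles; overlap is flagged.

## Synthetic generators (synthetic_data)

All generators are deterministic given their seed and record (seed,
parameters) in returned metadata.

* **Glucose** — dG/dt = −k_i E(t) G + k_r (G_b − G), fine-step Euler
  (0.05 min), sampled at the ITT times with additive Gaussian noise.  The
  coupling of effect E(t) to the cumulative drug past the capsule is this
  package's modelling choice, not an empirical claim; it exists to exercise
  the metric pipeline with realistic response shapes.  Defaults emulate the
  study conditions: cohorts of 5, baseline 150 mg/dL, noise 5 mg/dL,
  k_i = 0.035/min and k_r = 0.015/min (≈70% steady drop, ~20 min onset time
  constant for an unencapsulated device), lognormal animal effect on k_i
  with σ = 0.15 (chosen to give between-animal spread comparable to typical
  ITT error bars).  What passing tests show: the metric pipeline recovers
  programmed effects and orderings.  What they do not show: that real
  insulin pharmacokinetics follow this one-compartment coupling.
* **Fibre fields** — anti-aliased line segments with axial von Mises
  orientations (von Mises on the doubled angle); κ = 0 is isotropic.
* **Capsule bands** — programmed thickness profiles with optional sinusoidal
  waviness; the vertical cross-section is widened by √(1+slope²) so the
  programmed thickness holds along the band normal.
* **Point masks** — Gaussian-filtered noise thresholded at the matching
  quantile; realized fraction returned as ground truth.

## Problem sizes

The desk-scale scenario used throughout the tests, the analysis drivers and
the acceptance script is a 2.5 × 5 mm outer domain at 25 μm spacing
(100 × 200 cells; reservoir 0.5 × 2 mm) simulated for 200 s.  This is the
package's reference configuration for routine work: the capsule dominates
the transport resistance by ~8 orders of magnitude, so truncating the outer
domain changes peri-membrane and trans-capsule quantities only marginally
while keeping a full simulation under a few seconds.  The full 5 × 20 mm
domain remains the configurable default of `load_config` for production
runs.

## Known limitations

* 2D only; no fluid–structure interaction, membrane mechanics, or tissue
  strain — the actuation pressure acts directly as a boundary condition.
* First-order upwind advection is diffusive; during the short pulses this
  under- rather than over-states convective enhancement.
* The in-vivo effect sizes (e.g. a ~70% vs ~21% maximum glucose drop, or a
  thickness–efficacy correlation near −0.93) depend on unreleased animal
  data; the synthetic end-to-end demo reproduces their qualitative pattern,
  not their numeric values.
* The quasi-static flow assumption breaks down for actuation frequencies
  far above 1 Hz, where added-mass and compliance effects would matter.
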