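# Methods

## Model

The detector is a 32 × 32 lattice of vented pixel ionization chambers
(7.62 mm pitch, four corners unpopulated → 1020 chambers) with a 3 mm
absorber on top, the chamber layer at 3–8 mm depth, a 0.75 mm anode
layer at 8–8.75 mm, and 35 mm of internal backscatter. Its reference
measurement plane (OEMP) lies 3.5 mm below the surface and is set up on
the isocenter plane, 100 cm from the source.

The DEMP model asserts that under a beam at gantry angle θ the array
responds as if measuring on a plane displaced from the OEMP by `Δd(θ)`
(positive toward the detector bottom), with left–right symmetry
`Δd(θ) = Δd(360°−θ)`, and that the anode layer carries an effective
density ρ that lengthens the radiological path of beams entering from
below. Offsets are stored on the half-grid 0°–180° in 10° steps and
linearly interpolated in between, except strictly inside (80°, 100°)
and (260°, 280°), where the angular response can fluctuate erratically;
there the lookup refuses (or warns, configurable). Grid angles such as
90° are themselves served — only strict-interior interpolation is
blocked.

Assumptions worth keeping in mind: the model is a first-order, rigid
displacement of a single plane — it cannot represent off-axis variation
of the angular response within the detector plane, and it says nothing
about the excluded intervals.

## Dose engine (surrogate)

The DEMP method only needs *a* per-beam 3D dose; any commissioned TPS
would do. The built-in engine is a deliberately simple divergent-beam
primary model,

```
D(p) = MU · O · T(p) · f(r(p)) · (SAD/‖s−p‖)²
f(d) = (1 − e^{−β d}) e^{−μ d} / f(d*),   d* = ln((μ+β)/μ)/β
```

with `T` a separable product of error-function jaw-edge profiles
(σ = 3 mm at the isocenter, scaled with divergence) evaluated in
back-projected isocenter coordinates, and `r(p)` the radiological path
from the phantom entry to `p`. Defaults `μ = 0.046 cm²/g`,
`β = 2.8 cm⁻¹` place the depth-dose maximum near 1.5 cm (6 MV-like);
`O = 0.01 Gy/MU`. There is no scatter kernel or electron contamination;
heterogeneity acts only through the path integral, which is exactly the
channel the ρ mechanism uses.

Radiological paths are exact. Point queries traverse the voxel grid
Siddon-style. Whole-grid dose computation uses an equivalent analytic
route: slab phantoms carry their construction as axis-aligned
homogeneous boxes, so the path is body density × segment length inside
the phantom plus (ρ_box − body) × segment∩box for each override, fully
vectorized. Voxelization is partial-volume weighted at box boundaries,
which keeps the voxel array and the analytic description consistent
(the two routes agree to ~1e-3 g/cm² on oblique rays, exactly on
axis-aligned ones) and makes the 0.75 mm anode representable on a 1 mm
grid. Dose grids are windows around the planes to be extracted — the
upstream attenuation comes from the analytic path, not from the dose
grid — which is what makes whole-suite runs cheap.

## Calibration

Per plan i (gantry θᵢ): extract the planar dose at depth
`3.5 + Δd(θᵢ)` mm by trilinear interpolation, sample it bilinearly at
the chamber centers, and form the mean squared difference to the
measured grid; the cost is the sum over plans. The fit is bounded
least squares (`scipy.optimize.least_squares`, trust-region-reflective
LM variant) over 19 offsets (±20 mm) and ρ (1–9 g/cm³), from
`Δd ≡ 0`, `ρ = 2`. The Jacobian is forward-difference with fixed steps
(0.1 mm, 0.05 g/cm³) and exploits the structure: an offset column only
re-extracts a plane from the cached 3D dose of its own plan; the ρ
column triggers one engine pass over all plans. 3D doses are cached
keyed on ρ. Termination: relative cost tolerance 1e-4 (configurable) or
the iteration cap; the diagnostics carry the accepted-cost history,
per-plan residuals, the convergence reason, and Jacobian column norms
as parameter sensitivities — fitting AP-only angles reports a ρ
sensitivity of exactly zero, since AP rays never traverse the anode.

The calibration cost contains no detector-response convolution (an
optional `response_sigma_mm` exists for measurements known to include
volume averaging); correspondingly, synthetic *calibration* fixtures
are generated with volume-averaging σ = 0 so that the generator is the
exact forward model of the cost. On noiseless fixtures the joint fit
recovers injected offsets to < 0.01 mm and ρ to < 1e-6 relative; with
0.5% noise the median offset error stays ~0.01 mm, while the 90° offset
is nearly unidentifiable (an edge-on beam barely constrains its own
plane depth) — its error can reach millimetres, which is one more
reason the (80°, 100°) interval is treated as unreliable.

## Verification

Corrected composite: per-beam planar doses at the per-angle planes
(anode at the model's ρ), summed on a common 1 mm lattice; uncorrected:
identical but every plane at 3.5 mm. The calculated composite is
convolved with an isotropic Gaussian (default σ = 2 mm) representing
chamber volume averaging — applied to the final composite, before
gamma. The measurement is resampled from the 7.62 mm lattice to ~1 mm
by bilinear interpolation, endpoint-inclusive over the chamber square
(realized pitch 1.0009 mm) with the four corner sites filled by local
parallelogram extrapolation; no extrapolation beyond the outer
chambers.

Gamma follows the conventions used for array QA: the resampled
*measurement* is the reference and anchors both the global (Van Dyk)
normalization `D_max,ref` and the 10% low-dose ROI. The search is
exhaustive over a disc of radius 3 × DTA at a fixed sub-pixel step
(default 0.5 mm), with the evaluated distribution bilinearly
interpolated at each displaced position and an early exit once the
distance term alone exceeds every remaining pixel's current minimum.
A fixed-step search was chosen over local parabolic refinement because
it is verifiable against a brute-force oracle to 1e-6, which the test
suite does. The paired one-sided t-test is `scipy.stats.ttest_rel`
with the degenerate zero-variance case handled by convention
(p → 0/1 by the sign of the mean difference, 0.5 when all differences
vanish).

## Virtual detector and fixtures

`simulate_measurement` applies a ground-truth model forward: per-beam
3D dose with the anode at the truth ρ, planar extraction at the truth
plane, Gaussian volume averaging (default σ = 2 mm), chamber sampling,
beam summation, then seeded additive Gaussian noise (σ as % of the max
dose, default 0.5%) with negative values clipped to zero. The default
truth offset table grows monotonically from 0 at 0° to 10 mm at 180°
(oblique displacements of ~1 cm are the realistic scale) with
`Δd(130°) = 5 mm`. The test-plan suite contains eight open single-beam
plans (4×4 and 5×3 cm² at 0°, 50°, 130°, 180°), a seven-beam
conformal-like plan, and four pseudo-IMRT plans of 5–9 beams with 2–5
weighted rectangular segments each — stand-ins for the standard IMRT
commissioning tests, with every angle outside the excluded intervals.

What the generator does *not* emulate: MLC-shaped apertures and
leaf-end effects, scatter and electron contamination, detector drift,
setup error (available only as an explicit CF-curve offset), couch
attenuation, and any off-axis structure of the angular response. Green
tests therefore demonstrate the *self-consistency* of the
calibrate-correct-verify machinery under the stated mechanism, not the
clinical accuracy of a physical detector.

## Numerical choices and known behaviour

* Grids: voxel centers on multiples of the spacing, so the isocenter
  plane is grid-aligned; planar extraction at a grid plane is an exact
  slice. 1 mm vs 0.8 mm dose grids change chamber-sampled planar doses
  by at most ~0.03% of the max over the calibration plans.
* Study sizes: the heavier suite studies (joint calibration, noise
  replicates) run on a 2.5 mm dose-grid window — forward simulation and
  calibration share the grid, so the scale-down does not bias the
  recovery they measure.
* The reproduced CF curve is 1 at 0°, symmetric under θ → 360°−θ, and
  most angle-sensitive just above the excluded interval, where the
  displaced plane traverses the anode layer. With this engine and slab
  phantom the largest finite-difference |dCF/dθ| lands in (120°, 130°);
  physical detectors have been reported most sensitive slightly lower,
  in (100°, 120°) — the location depends on the beam-entry geometry and
  the engine's lateral-entry handling, not on the offset table.
* Noiseless end-to-end self-consistency passes 3%/3 mm at 100.0% for
  the oblique 4×4 beam, but 3%/2 mm saturates near ~93%: bilinear
  resampling of a 7.62 mm lattice across a ~3.6 mm-σ penumbra leaves
  residuals equivalent to ~2 mm displacements. This mirrors array QA
  practice, where 3%/2 mm rates of sharp single fields sit below 100%
  even for well-corrected systems.
* Gamma pass boundary: γ = 1 passes; an evaluated field offset by
  exactly the dose tolerance lands on the boundary up to binary
  rounding (~1e-16 in γ²).
* Degenerate inputs refuse loudly: zero reference maxima (gamma,
  percent error), non-overlapping extents, chambers outside a planar
  extent, planes outside the dose grid, excluded-interval angles under
  the error policy.

## Limitations

The engine is primary-only; absolute dose levels and scatter-sensitive
configurations are out of scope. The model offers no prediction inside
(80°, 100°)/(260°, 280°). Calibration quality at near-edge-on angles is
intrinsically weak. File formats are the package's own text dialects
plus YAML/JSON; proprietary array formats are not read.
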