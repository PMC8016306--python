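# Methods

This note documents the models, numerical choices, and limitations behind
`tactillusion`. Units are mm / kPa / mN internally (1 kPa·mm² = 1 mN);
public interfaces use newtons.

## The scientific setting

When a fingertip presses a compliant sphere, the skin receives *cutaneous*
cues — the stress and strain-energy-density (SED) fields at the
epidermal–dermal interface where mechanoreceptor end-organs sit, the
deflection of the skin surface, and the gross contact area — while the
musculoskeletal system receives *proprioceptive* cues, chiefly the
fingertip displacement needed to reach a given contact force. For
spherical stimuli whose elasticity and curvature co-vary in a compensating
way, the cutaneous cues of a small-compliant sphere (shear modulus 10 kPa,
radius 4 mm) and a large-stiff sphere (90 kPa, 8 mm) become nearly
identical, while their force–displacement relations stay distinct: the
elasticity–curvature illusion. The package simulates this mechanically,
implements the measurement analytics used to test it (ink contact areas,
force-trace processing), and scores same–different discrimination
behavior with the differencing-rule d′.

## Contact mechanics model

### Constitutive law

Every soft body uses a compressible Neo-Hookean strain energy

Ψ = C₁₀(Ī₁ − 3) + (1/D₁)(J − 1)²,  Ī₁ = J^(−2/3) tr(F Fᵀ), J = det F,

with shear modulus G = 2C₁₀ and bulk modulus K = 2/D₁. Tissue layers
default to near-incompressibility, K = 10⁵·G (configurable). The
hemispherical stimulus tip uses a Poisson ratio of 0.475 (K ≈ 19.7·G),
mimicking nearly incompressible silicone rubber. The Cauchy stress is
σ = (G/J)·J^(−2/3)·dev(B) + K(J−1)I; a finite-difference check of the
stress against the energy gradient is part of the test suite.

### Geometry

The finger pad is a parameterized layered domain: epidermis (0.470 mm, so
the mechanoreceptor interface lies 470 μm below the surface), dermis
(1.2 mm) and subcutaneous tissue (4.0 mm) over a rigid bone proxy
(clamped base). The contact surface is flat in the reference
configuration with a radial extent of 18 mm; the cue-sampling window
spans 0–15.2 mm of arc with 111 equally spaced interface nodes in the
default configuration (56 in the coarse preset), continuing with
geometric coarsening beyond. Default layer shear moduli (epidermis 45.9,
dermis 27.0, subcutaneous 11.5 kPa) are literature-typical values for
fingertip skin; they put the composite pad stiffness in the tens of kPa
range at contact scales, which is the regime in which
elasticity–curvature compensation between a soft-small and a stiff-large
sphere is mechanically possible at all.

The stimulus tip is a hemisphere meshed from a structured square-to-disk
map (no degenerate cells), its flat face tied to the rigid driver in the
normal direction. A normal-only (frictionless) tie was chosen over a
fully bonded face: bonding creates a shear singularity at the plate rim
that collapses elements of the softest tip well before the 2 N terminal
load, while the normal tie transmits the same load robustly.

Two 2D formulations share one element implementation: axisymmetric
(normal contact; all cue simulations) and plane strain (a cross-section
across the finger width; used for deflection calibration).

### Discretization and solver

Bilinear quadrilaterals with an F-bar (element-mean dilatation)
modification carry the near-incompressible response without volumetric
locking. The Newton tangent contracts the material stiffness dP/dF —
obtained by central differencing of the analytic first Piola–Kirchhoff
stress at each quadrature point, vectorized over elements — against the
full dF̂/du including the mean-dilatation coupling; the assembled
stiffness matches a finite difference of the internal force to ~1e-9
relative, which is what makes Newton quadratic at K/G = 10⁵.

Contact is a frictionless penalty on the *vertical* gap between the
fingertip surface nodes (slave — always the finer discretization) and the
piecewise-linear underside of the stimulus (master). Aligning the contact
normal with the drive axis suits the axisymmetric normal-contact geometry
and eliminates the normal-rotation chatter that a segment-normal
node-to-segment scheme exhibited once the soft tips squash deeply. The
penalty stiffness is 100 × (softer body's G) / (surface spacing),
configurable. A rigid spherical/cylindrical indenter option (analytic
master surface) serves the calibration runs.

Force control is an outer loop on rigid-driver travel: adaptive travel
stepping with warm starts (including a rigid-translation predictor for
the driven body), then damped Newton continuation on the monotone
force–travel relation until each scheduled force matches within 1%.
Passive mode drives the stimulus plate into the fixed pad; active mode
drives the pad base into the fixed stimulus; by frame invariance both
yield the same contact state at equal force (verified to a cue distance
of ~1e-4), so the proprioceptive cue (driver travel at force) can be read
from either.

Convergence: residual 2-norm ≤ 1e-3 × the transmitted contact force,
or a displacement increment below 1e-6 mm. All solves are deterministic.

### Verification

* **Hertz oracle** — a near-rigid sphere (G × 10⁴) on a single-material
  half-space at 0.01 N (<5% strain) reproduces the closed-form contact
  radius and peak pressure within ~2–4% at the meshes used in the tests.
* **Energy** — external work along the load path bounds the stored
  energy, equal within ~1% for rigid indentation and for the stiff
  stimulus at all loads. For the softest tip (10 kPa–4 mm) beyond ~1 N
  the sphere is squashed to extreme strain and the F-bar internal force
  is no longer an exact energy gradient; stored/work drifts to ~1.10 at
  2 N. This does not affect equilibrium itself (force balance holds to
  the solver tolerance) but is a known limitation of the element at
  extreme distortion.
* **Mesh stability** — halving the element size changes the interface
  stress profile by ~3.5% RMS and the deflection profile by ~0.6%.

### Cue extraction

Interface stress and SED profiles assign each of the 111 interface nodes
the arithmetic mean of its adjacent elements' values (von Mises stress by
default; the normal component is available). Surface deflection is the
normal displacement of the epidermis-surface nodes, measured relative to
the bone in active mode. Profiles are compared with a normalized RMS
distance (RMS of the pointwise difference over the RMS of the pooled
values, after linear resampling to the common arc range): 0 means
identical, values near 1 mean dissimilar.

### What the model reproduces — and what it does not

With the default calibration the illusion emerges from the physics: at
every load in {0.25, 0.5, 1, 2} N and for all three cutaneous cues, the
illusion pair (10 kPa–4 mm vs 90 kPa–8 mm) is 2–5× closer in cue distance
than the illusion-vs-distinct pair (10 kPa–8 mm), while the
force–displacement curves of the illusion pair remain separated by >1 mm
at 2 N. One secondary ordering differs from intuition: at 2 N the very
soft *large* sphere (10 kPa–8 mm) requires slightly more travel than
10 kPa–4 mm, because in the deep-squash regime the taller soft column
compresses more; the headline separation (soft-small vs stiff-large) is
unaffected.

## Material calibration

Calibration is two-step. Step 1 fits the dermis:epidermis and
subcutaneous:epidermis modulus ratios by grid search (default 5×5):
the plane-strain model is indented by a rigid 0.5 mm cylinder to 0.4,
0.8 and 1.2 mm and the predicted surface-deflection profiles are scored
with R² against target profiles; the selected ratios are the mean of all
grid points with R² ≥ 0.8. Because the fields under displacement control
are invariant to a global modulus scale, the ratio fit is exactly
separable from step 2. R² is evaluated only in a lateral sensitivity band
(0.8–2.0 mm): in-contact deflections are clamped to the indenter shape
and far-field tails vanish for every model, so both regions carry no
layer information and would only inflate R². Even so, the deflection
observable constrains the two ratios jointly along a soft "equivalence
ridge" (lowering both ratios together changes the profile little); the
threshold-averaging rule returns the ridge center, which is why the
recovery guarantee is stated in units of grid spacing rather than
percent.

Step 2 fixes the absolute scale against a force–displacement target
(rigid 5 mm spherical indenter, axisymmetric model): the model is solved
once at a reference modulus and a single scale factor minimizing the
squared force error is found by golden-section search (the predicted
force is proportional to the scale, again by homogeneity). With the
generating ratios the scale recovers to <0.1%; grid-resolution error in
the ratios propagates into the scale fit accordingly.

Calibration targets ship as synthetic curves generated by the mechanics
module itself at known moduli (the original deflection and
force–displacement measurements are not redistributable), with optional
Gaussian noise.

## Measurement analytics

**Ink contact area.** Pixel scale comes from a 5.0 cm reference bar
(annotated in a sidecar, or auto-detected as the longest dark horizontal
run). Ink pixels are thresholded in HSV (saturated or dark) inside an
explicit analyst ROI (center + radius), cleaned with a small
morphological opening/closing, and the exterior outline of the largest
connected component is traced along pixel edges (a serial crack-following
boundary search). The outline's shoelace (Gauss) area equals the enclosed
pixel count exactly, so rasterized disks are recovered to <0.1% and the
synthetic end-to-end pipeline to <3% including speckle noise; holes are
not subtracted (the measurement is defined on the exterior outline).

**Force/displacement traces.** Traces are smoothed with a 100-reading
moving average (shrinking symmetrically at the edges so constants pass
through; the window shrinks to a third of short traces). The loading
ramp is the longest run where the first difference exceeds 20% of the
peak positive derivative (ascending limb only). The force-rate is the
OLS slope over the ramp after trimming one filter window from each end —
the filter rounds the ramp shoulders and including them biases the slope
low; with the trim, protocol rates of 0.5/1/2 N/s are recovered within
1% at 0.02 N sensor noise. Net fingertip displacement is the absolute
difference of the (smoothed) laser channel between the force-ramp
boundaries.

## Psychophysics

The same–different task over the three illusion spheres uses all 9
ordered pairs (sampling with replacement), presented 2× per passive task
and 3× in the active task, in seeded randomized order. Sensitivity uses
the differencing rule: one unit-variance observation per interval, the
observer responds "different" when |difference| exceeds a criterion k, so
F = 2Φ(−k/√2) and H = Φ((d′−k)/√2) + Φ((−d′−k)/√2). (k is expressed on
the difference axis, whose standard deviation is √2.) The inversion
solves k from F in closed form and d′ by bracketed root finding; it is
the exact inverse of the forward model to 1e-6, agrees with a 10⁵-trial
Monte-Carlo observer within 2%, and returns d′ = 0 whenever H ≤ F.
Extreme rates are corrected by 1/(2N). Per-condition d′ is reported both
from pooled counts and as the unweighted mean of per-pair d′ (each
different-pair scored against the condition's same-pairs).

The synthetic observers default to d′ = 0.4 / 1.2 / 2.5 / 3.5 for the
passive-same, passive-inverse, passive-direct and active conditions —
placeholders spanning chance to high sensitivity in the qualitative
order of the behavioral conditions, not estimates of human values.

## Statistics

Mann–Whitney U reports min(U₁, U₂) with midranks; for n·m ≤ 64 the
two-sided p is exact by enumerating all group assignments (P(min-U ≤
observed) under the permutation null), otherwise a tie- and
continuity-corrected normal approximation is used. Cohen's d is the
absolute standardized mean difference with the Bessel-corrected pooled
SD. Confidence intervals are seeded percentile bootstraps (1000
iterations); on Gaussian samples of n = 100 the 95% interval covers the
true mean 94.9% of the time over 1000 replications (92.7% at n = 50 —
the familiar O(1/n) undercoverage of the percentile method). The
sigmoidal membership normalization (logistic centered at the sample
mean, growth rate 1) is applied per participant and per task before
pooling; it is strictly monotone up to floating-point saturation.

## Synthetic data: what it emulates, and what it does not

The generators emulate the study's *protocols and noise structure*:
triangle-wave indentations peaking at 1/2/3 N, constant-rate ramps at
0.5/1/2 N/s to 2 N with Gaussian sensor noise, laser displacement traces
derived from a force–displacement relation, ink stamps as elliptical
blobs (known pixel-exact area, 5 cm bar, speckle), and full
same–different sessions from the differencing observer. Generating mean
contact areas follow the study conditions (illusion set ≈ 0.90 cm²,
distinct ≈ 1.68 cm² at 2 N in passive mode, 0.87/1.48 in active mode,
with Hertz-like growth in force and per-participant offsets). Every
generator is a pure function of (spec, seed).

What passing tests on these data do *not* show: real fingerprints are
ridged, irregular and smudged rather than elliptical; real observers
drift, lapse, and differ between participants beyond a scalar d′; real
sensor noise is not white. The synthetic loop validates the analysis
machinery, not human behavior — the printed human percentages and areas
are inherently participant-dependent and are treated as generating
conditions, never as recovered results.

## Problem sizes used

Routine runs use the coarse fingertip preset (56 interface nodes,
8 element rows, ~500 elements) with a 2× coarsened stimulus mesh; the
structural default (111 nodes) is built whenever the interface sampling
itself matters. The Hertz benchmark uses a dedicated half-space mesh
(41 surface nodes over 3 mm, 16 rows). The calibration grid search runs
25 plane-strain solves of ~250 elements. These sizes keep a full
verification cycle in minutes on one CPU while staying within the
convergence plateaus reported above.
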