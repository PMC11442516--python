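# Methods

This note documents the models behind `sonoservo`, the parameters that
matter, the numerical choices, and the limits of what the simulation can
show.

## Coordinate conventions

Four frames chain the system: robot base {b}, flange {f}, probe tip {p} and
ultrasound volume {vol}. Transforms are 4×4 homogeneous matrices with
runtime-checked frame names; `bT_vol = bT_f · fT_p · pT_vol`. Pixel
coordinates are (x, y) = (column, row), origin top-left, 0-based. The probe
frame has z pointing into the tissue and x along the vessel (elevational
direction); the cross-section image spans probe y (columns) and probe z
(rows). Lengths are millimetres in the phantom/imaging world and metres in
the arm/control world; the conversion happens exactly once, at the
probe–skin boundary.

The image x-axis direction relative to probe y is a property of the
ultrasound station's display, not of the geometry — which is precisely why
the rotation-sign calibration experiment exists. The phantom models both
conventions (`lateral_flip`); the default corresponds to the R2 case (image
x and probe y aligned), and the simulated experiment recovers R2/R1
accordingly.

## Phantom

The vessel is a parametric centerline in the base frame,
`(ox + u, oy + A·sin(2πu/λ), −d_v)` for axial coordinate u, with radius
profile `r(u) = r0·(1 − taper·u/L)`. Defaults model a superficial femoral
artery scan: r0 = 5 mm (the cluster-merge threshold of 50 px ≈ 4.9 mm is
stated to be about one artery radius), depth d_v = 20 mm, lateral amplitude
A = 5 mm, wavelength λ = 100 mm, length 250 mm, taper 0 (tests that need
appearance deformation set 30–35 %).

B-mode appearance is deliberately simple: a depth-attenuated background,
tissue-anchored texture (a fixed sum of six 3D sinusoids of world
coordinates, so structures translate correctly under probe motion — each
frame's plane is affine in (row, col), letting every sinusoid factor into
outer products of 1D terms), multiplicative gamma speckle
(`speckle_noise_level` mixes it in, default 0.3), a bright skin line, and
the lumen as a soft-edged dark ellipse with a thin echogenic wall. No wave
propagation, shadowing, or refraction is simulated.

Doppler cross-sections paint the lumen with red pixels drawn from hues
{2, 5, 8, 174, 178}, saturations ≥ 130 and values ≥ 80 — all safely inside
the tracker's red gates after the uint8 RGB round trip. The flow radius
pulses with a 1 s cardiac period (0.78 + 0.18·sin phase). With probability
`fragment_probability` per frame (default 0.3) the patch is cut by one or
two random stripes at least 2.5 px wide (wide enough that 8-connected
labelling cannot bridge them), splitting it into ≥ 2 disjoint areas whose
area-weighted centroid stays near the lumen center — the failure mode the
cluster-merging step exists to fix. The longitudinal X-Plane image is
rendered for completeness only; the trackers consume the cross-section, so
no longitudinal tracker is invented.

Per-frame randomness (speckle, fragmentation) is keyed by
SHA-256(salt, quantized timestamp) under the config seed: identical
config + seed + time ⇒ bit-identical frames, while different frames and the
two imaging modes decorrelate.

Skin contact is a height surface with a normal spring–damper
(default 1 N/mm, 0.05 N·s/mm; ~5 mm indentation at the 5 N target, a
soft-tissue scale). The contact wrench is reported as the wrench the probe
exerts on the skin, so its force component along the probe z-axis is ≥ 0 and
vanishes without penetration. This sign convention makes the compliant law's
force term vanish exactly at equilibrium, mirroring how a torque-sensing
robot experiences a balanced desired wrench.

## Trackers

The correlation search uses the *non-centered* normalized correlation
coefficient (no mean subtraction): values are bounded by 1 for nonnegative
images with equality exactly at proportional patches, and placements where
the image patch has zero energy score 0 by convention. Small inputs are
correlated directly (exact for integer-valued images, which the oracle tests
exploit); large ones via FFT, with the local energy clipped at 0 against
roundoff. Candidates are 8-neighbourhood local maxima with positive score,
tie-broken in row-major order, greedily separated by a quarter template
side, and reported at the template *center* — avoiding the classic
half-template systematic offset. The template is cut once at the scan start
and never updated, matching the studied protocol; a refresh interval exists
as an opt-in config but defaults to off.

Doppler extraction converts RGB to HSV via scikit-image and rescales to the
H ∈ [0,180], S,V ∈ [0,255] convention the stated thresholds assume. An
exact prefilter (red hues force R to be the strict channel maximum) limits
the conversion to the bounding box of candidate pixels. Components are
8-connected (diagonally touching pulsatile fragments should not split);
regions under 5 px are dropped as color noise (the threshold is config).
Merging is greedy and largest-first: the current cluster absorbs any
remaining region whose centroid lies strictly within T_cl of the running
area-weighted centroid, recomputing the centroid after every absorption and
re-scanning until stable, then continues from the next largest unclaimed
region. Whether the original procedure re-scans after each merge is not
fully specified; this greedy reading conserves total area and keeps every
cluster centroid inside the members' bounding box, both asserted as
properties.

The plausibility update accepts the candidate nearest P^{t−1} iff its
distance is ≤ T_d = 50 px, else retains P^{t−1} (also when no candidate
exists). Distance ties take the earlier candidate in rank order. An
uninitialized tracker raises: the initial position is an operator decision,
emulated in the closed loop by seeding with the first frame's true center.
No correlation floor is applied before gating — candidates are filtered by
distance only, with the positive-score requirement as the only floor.

## Calibration

R1 = (0,0,−1; −1,0,0; 0,1,0) and R2 = (0,0,1; 1,0,0; 0,1,0) are stored
as literal rows; multiplying [R1 | (l/2·s_x, w/2·s_y, 0)] by
S = diag(s_x, s_y, s_z, 1) reproduces the documented sparsity pattern
entrywise, which the tests assert rather than re-derive. o_z is neglected:
it is only the transducer standoff, irrelevant for directional servoing.
The displacement experiment defaults to a 5 mm move — about one vessel
radius: large enough for an unambiguous shift (≈ 51 px), small enough to
keep the structure in view; the magnitude is config. A zero measured shift
raises an inconclusive-calibration error telling the operator to repeat
with a larger move.

## Arm and control

The arm is a generic 7-revolute iiwa-like chain (0.34 + 0.4 + 0.4 m links,
alternating z/y axes, 0.126 m wrist, 0.06 m flange plate, 0.2 m probe);
any full-row-rank 7-DoF chain exercises the redundant control law
equivalently, so no specific commercial kinematics is claimed. Forward
kinematics and the geometric Jacobian come from the chain directly (hot
path uses an inline Rodrigues formula); a damped-least-squares IK with an
analytic planar elbow warm start places the arm at the scan start.

The compliant law is implemented as `q̇_c = D⁻¹(Jᵀ F_d − τ_ext) + J† V_d`
with D = d_i·I applied on the left of the force-error term (the only
dimensionally consistent reading) and F_d = (0,0,f_d,0,0,0)ᵀ expressed
along the probe z-axis and rotated to the base frame before use. J† is the
explicit right pseudoinverse Jᵀ(JJᵀ)⁻¹; a condition number of JJᵀ above
1e8 raises a singularity error and the loop aborts rather than commanding a
near-singular velocity.

The inner joint impedance controller is approximated by a first-order
velocity-tracking lag with time constant 2ζ/ω_n, ω_n = √(k/I_eff)
(defaults k = 500 N·m/rad, ζ = 0.9, I_eff = 1 kg·m² ⇒ ~80 ms). Joint
inertia, friction and hysteresis are not modelled and the simulated torque
sensing is exact, so the force loop converges to f_d with no steady-state
deficit — unlike a hardware system, whose torque-estimation errors produce
an offset of a few tenths of a newton. Simulated force results therefore
validate the *law*, not a hardware force-estimation chain.

## Closed loop

Frames are rendered at the mode's acquisition rate (10 Hz Doppler, 25 Hz
B-mode) and the visual decision — advance along the vessel, or move
laterally toward it when e_c exceeds 50 px (strict inequality) — is held
over the frame period, while the force/motion law is re-evaluated at the
200 Hz control rate underneath; closing the force loop only at the imaging
rate is unstable for stiff contact, exactly why real systems separate the
two rates. Corrective and advance motions are mutually exclusive, matching
the stated if/else protocol. Advance and corrective speeds default to
5 mm/s each, chosen so a 200 mm scan takes on the order of 40 simulated
seconds, in the range of the reported scan times; they are config values,
not assertions. A scan starts with a contact-settling phase (the force loop
runs with V_d = 0 until f_z is within 0.1 N of f_d), standing in for the
physician placing the probe before the automatic scan begins. Distance from
the start is the running maximum of the probe's displacement projected on
the vessel axis, making the logged distance nondecreasing under the small
lateral coupling of the force term. Tracking is declared lost after 25
consecutive retained (non-accepted) frames — the plausibility tracker never
loses lock by construction, so a stop rule is needed; the count is config.

The template path restricts the correlation search to a window of
half-width T_d + template half-size + 10 px around P^{t−1}. Any candidate
that could pass the distance gate lies inside that window, so accepted
decisions are identical to a full-image search (asserted by a test); the
full-image search remains the module-level API.

## Evaluation

Metrics follow the scan protocol's evaluation: per-frame tracking error
against ground truth
in px and via the 0.098 mm/px spacing in mm, binned by distance from the
scan start (20 mm bins), contact-force statistics per bin, corrective-move
episode counts, scan times, and the relative improvement
(e_A − e_B)/e_A between two methods.

Simulation sizes used by the test suite and the acceptance script: one full
200 mm scan per tracker for recovery and timing; the Doppler-vs-template
robustness ordering uses 100 mm scans over 10 seeds on a 35 %-tapering
phantom and compares medians of the per-scan mean errors; the force loop is
simulated for 3 s at 5 ms steps.

## What passing tests do and do not show

The phantom gives the trackers an almost ideal target: the flow patch is
exactly centered on the lumen, backgrounds contain no competing red pixels,
and no out-of-plane motion, probe tilt, shadowing or signal dropout occurs.
Sub-pixel Doppler errors and ~0.5 px template errors on the phantom
therefore demonstrate correctness of the pipeline, not clinical accuracy:
in vivo, speckle decorrelation, tissue deformation, imperfect probe coupling
and labeling uncertainty put realistic tracking errors of this method class
around 10–14 px. The qualitative behaviour the
simulation does reproduce is the *ordering*: when the vessel's appearance
deforms along the scan, the start-of-scan template degrades while the flow
centroid stays well defined, so Doppler tracking is the more robust of the
two. Vein/artery discrimination by flow color, neural segmentation,
DICOM/streaming ingestion and real-time guarantees are out of scope.
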