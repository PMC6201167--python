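# Methods

This note documents the model behind `stafree`, the numerical choices made
where the design was genuinely open, what the synthetic gait fixture does and
does not emulate, and the known limitations.  Every empirical statement below
is computed by the test suite or by `scripts/acceptance.py`; nothing is quoted
from elsewhere.

## Model and assumptions

A planar multi-rigid-link system is observed through two skin markers per
link over exactly one movement cycle of N uniform samples (the cycle is
closed: sample N+1 ≡ sample 1).  Three frames per link matter:

- the **landmark frame**: origin at the midpoint of the link's two anatomical
  landmarks, x-axis from landmark 1 to landmark 2 — rigidly link-fixed but
  unobservable;
- the **marker frame**: the same construction applied to the captured
  (artifact-contaminated) markers — observable but *not* link-fixed;
- the **link frame**: CoM-anchored evaluation frame, x-axis toward the distal
  end, at a constant transform from the landmark frame supplied by the
  topology's landmark geometry.

Assumptions: all joints are ideal pins; the soft-tissue artifact (STA) of
each marker, expressed in its link's landmark frame, is periodic with the
movement and band-limited to Fourier order K (default K = 4, adequate for the
low-pass character of gait-cycle artifact); the data span exactly one cycle
(segmentation is the caller's responsibility); markers are noise-free apart
from the STA (no additive sensor noise model).

A structural identifiability fact shapes the whole design: the artifact's
cycle-mean (DC) is absorbed into where the landmark is taken to be, so the
expansion deliberately carries no constant term and only the zero-mean
artifact is recoverable.  Likewise the transverse coefficient difference
enters the data only through its square, leaving a per-link sign gauge
`ξ_y → −ξ_y` and, more generally, a *discrete set* of shape solutions.

## Stage 1: shape identification per link

The squared inter-marker distance equals `(C + P[n]ξ_x)² + (P[n]ξ_y)²`;
Fourier-matching it against the measured distance series gives 4K+1 equations
in 4K+1 unknowns.  The term-wise matching is realized numerically — evaluate
the model series on the grid and project onto the DC + order-2K basis — which
is identical to the symbolic product-to-sum expansion for band-limited series
(asserted in the tests against a sympy oracle at K = 1), and requires
N ≥ 8K+2.

Rather than a single root search, `solve_shape` enumerates the complete
solution set.  Writing `z[n] = (C + P[n]ξ_x) + i·(P[n]ξ_y)`, the data series
is `|z|²`, a positive trigonometric polynomial, and every factorization
`|z|² = D` with `z` of half the degree corresponds to choosing one root from
each reciprocal-conjugate root pair of the associated degree-4K algebraic
polynomial (Fejér–Riesz).  Each choice yields an exact solution of the 4K+1
equations; the global phase is fixed by making the DC of `z` real and
positive, which also excludes the `(−C, −ξ_x)` gauge copy, and candidates
with a non-positive axial separation (markers crossing) are discarded.  The
candidate nearest the naive initialization is polished by a Newton root solve
(`scipy.optimize.root`, hybr, tolerance 1e-13) on the residual vector and
must meet a residual tolerance of 1e-9·γ (γ = the distance-squared DC); the
full ranked list is retained for stage 2.

Why enumeration instead of the plain Newton-from-initialization search: the
natural initialization expresses each marker in its own link's marker frame,
and in that frame the markers sit on the x-axis *identically*, so the
transverse initial coefficients are exactly zero — precisely the saddle of
the quadratic system where the Jacobian in the transverse directions
vanishes.  A Newton iteration cannot leave it.  The transverse information is
genuinely second-order in the data; enumerating the factorizations recovers
it exactly and moves the selection problem to where the information actually
is, the joint constraint.  The initialization still earns its keep: initial
`C` and `ξ_x` (first-order accurate) plus an approximate marker-frame tilt
series (marker axis versus a naive-joint-based axis, mean-subtracted — valid
because any link-fixed axis is at a constant angle to the landmark axis) rank
the candidates so the true one is usually scanned first.

## Stage 2: linear joint-constraint solve and candidate selection

With `(C, ξ)` fixed, each marker frame's tilt relative to its landmark frame
is known in closed form (two-argument arctangent, branch-safe), and the
joint-constraint residual — adjacent links must predict the same global joint
position at every sample — is linear in the per-link marker-1 coefficients
(4K each) and the per-(link, joint) constant local positions (2 each).  For
the seven-link model at K = 4 this is 136 unknowns against 12N equations.  It
is solved as ordinary linear least squares (the sum-of-norms cost of the
source formulation is minimized as a sum of squares, which is what makes the
problem exactly linear; both cost values are reported), with rank, condition
number and any null space beyond 1e-10·σ_max surfaced in the report, never
hidden.  On the fixture the system is full-rank with condition ~2e4.

Spurious-candidate selection uses a decisive local property: for the *true*
candidate pair of the two links sharing a joint, that joint's own subproblem
(its rows only, with both links' coefficients and joint locals free) has
exactly zero residual, independent of the rest of the chain, while a wrong
pair generically cannot be absorbed by the 4K+2 free parameters per side.
`assemble_solve` therefore scans candidate pairs per joint
(initialization-ranked, early exit at a numerically zero subcost) and assigns
each link the candidate from its most decisive joint.  Greedy single-link and
per-joint pairwise descent over the full-system cost remain as a fallback;
plain greedy descent alone was observed to lock into coupled wrong
configurations spanning several links, which is why the per-joint selector is
primary.  After any selection change the chosen shapes are re-polished
against their spectra and the linear stage is re-solved once.

Reconstruction then strips the identified excursion and tilt from the marker
frames, places the landmark markers at ±C/2 on the landmark axis, predicts
each joint from both adjacent links and averages the two predictions, and
derives link frames, joint angles (clockwise-positive, distal relative to
proximal; root tilt from vertical) and per-link length series.

## The naive baseline

The baseline fits constant local joint positions directly to the marker
frames (one linear least-squares problem per joint, degenerate-motion
rank checks included) and takes each joint as the midpoint of the two
predictions.  It is exact on artifact-free data (machine precision, asserted)
and is deliberately left uncorrected otherwise — it is both the comparison
baseline and the initialization source.

## The gait fixture

The fixture replaces a forward-dynamics walking simulation with *prescribed*
band-limited periodic joint-angle trajectories — the assimilation algorithms
consume kinematics only, so nothing in the evaluation depends on how the
motion was produced.  Default conditions: seven-link body
(masses 40.548/6.882/3.162/0.682 kg, lengths 0.536/0.420/0.379/0.122 m, CoM
offsets 0.204/0.200/0.154/0.050/0.079 m, inertias 1.09933/0.09485/0.03001/
0.00014 kg·m²), N = 200 samples over a 1 s cycle, angle ranges hip ±0.35 rad,
knee 0–1.1 rad, ankle ±0.3 rad, HAT tilt ±0.05 rad, legs half a cycle out of
phase.  The HAT translation is purely periodic: the motion is expressed in
the frame co-moving with the average progression velocity, which is inertial,
so inverse dynamics are unaffected and every series is exactly periodic
(making spectral differentiation consistent).  Landmark placements use the
anatomical names as stand-ins (C7/xiphoid on HAT, joints at the thigh/shank
ends, heel/metatarsal on the foot) at link-frame coordinates derived from the
segment parameters; they are configuration, not inference.

STA injection draws coefficients per marker and axis uniformly in ±amplitude
with 1/k harmonic decay (default amplitude 0.01 m — the
millimeter-to-centimeter scale of skin-marker artifact in gait), seeded;
seven seed presets stand in for seven subjects.  The artifact is added in the
landmark frame and rotated out to the global frame, matching the model's own
construction exactly.

The synthetic GRF is a smooth double-hump vertical profile per foot, exactly
zero in swing, cycle-mean total equal to body weight, with a small
anterior-posterior shear and a heel-to-toe center-of-pressure progression; it
is *not* dynamically consistent with the prescribed motion and does not need
to be, because identical GRF is supplied to the true and the assimilated
inverse dynamics.  Torque is affine in the applied GRF at fixed kinematics,
so with a shared GRF the torque difference contains no GRF term once the
kinematics agree; note the difference between two *different* kinematics does
retain GRF-dependent moment-arm terms (both facts are asserted in the tests).

What passing on this fixture does and does not show: it validates the
algorithm's central claim — on exactly rigid, exactly periodic data with
band-limited STA, recovery is exact to numerical precision (~1e-12 rad at
N = 200; the acceptance thresholds of 1e-6 rad / 1e-6 N·m / 1e-6 m are
comfortably met for all seven seeds).  It does not exercise additive sensor
noise, aperiodic artifact components, cycle-segmentation error, marker
dropout, or non-pin joints; on real data those terms bias the recovered
coefficients in proportion to their size.

## Inverse dynamics

Standard planar recursive Newton–Euler per leg, foot → shank → thigh, with
the per-foot GRF applied at its center of pressure; left and right hip
torques come from their own leg recursions (no residual redistribution
through the HAT).  Accelerations come from spectral differentiation — fit a
truncated Fourier series (default order (N−2)/4), differentiate term-wise,
re-evaluate — exact for band-limited signals and free of finite-difference
noise amplification at the seam.  Gravity is 9.81 m/s²; torques are reported
clockwise-positive to match the angle convention.

## Numerical choices and degenerate inputs

- Coefficient ordering is cosines k = 1..K then sines; sampling is n = 1..N at
  phases 2πn/N with no duplicated endpoint; fits are least squares on the
  uniform grid (equivalent to DFT truncation), so any N is first-class.
- Rotations are stored as matrices (authoritative) with angles extracted via
  `atan2`; angle series are unwrapped around the cycle with the mean brought
  into (−π, π].
- Coincident marker pairs (< 1e-9 m), insufficient relative rotation at a
  joint (rank/condition checks, two-instant condition threshold 1e8),
  markers-crossing shape parameters, and aliasing fits (K ≥ N/2) all raise
  typed errors naming the offending link, joint or sample.
- The two-instant joint solve is kept as a closed-form utility and test
  oracle; production joint locals always come from the all-samples linear
  stage.
- Factorization trims spectrum coefficients below 1e-12 of the largest, so
  lower-order artifact (including zero STA, where the candidate set collapses
  to `ξ = 0`) is handled without spurious near-zero roots.

## Limitations

Planar, two markers per link, pin joints only; one cycle at a time (no
multi-cycle averaging); periodic, band-limited STA; the artifact's DC and any
rigid-with-the-link component are unidentifiable by construction; candidate
enumeration is exponential in the effective artifact order (2^(2K) worst
case — cheap at K = 4, impractical far beyond); no occlusion or dropout
handling.  Extension to 3-D (three markers per link, more distance
identities) changes the counting of unknowns versus equations and is out of
scope here.
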