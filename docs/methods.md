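# Methods

## Scope and design

`fontanflow` implements the quantitative analysis of 4D flow MRI in the
total cavopulmonary connection (TCPC): pathline-based caval flow
distribution, voxel-wise flow energetics, the preprocessing those
measurements require, and the longitudinal statistics applied to the
regional metrics.  Patient velocity data are not part of the package;
every stage is exercised on synthetic phantoms whose ground truth is known
analytically, so each operation can be validated independently of
acquisition.

## The TCPC phantom

The phantom is a planar cross junction: a vertical channel (half-width
W = 12 mm) carries the IVC upward and the SVC downward, a horizontal
channel carries the LPA (left) and RPA (right) outflows; limbs extend
40 mm beyond the junction and the 2D field is extruded over a 24 mm slab
with zero out-of-plane velocity.  The default acquisition grid is
anisotropic (2.4 × 2.0 × 2.4 mm) with 20 frames of 40 ms — a cardiac cycle
of 0.8 s — matching pediatric 4D flow protocols in spirit; venc defaults
to 120 cm/s and the mean IVC inflow speed to 0.3 m/s with an SVC:IVC flow
ratio of 2:3 (the usual Fontan caval balance).

**Exact flow splits.**  The in-plane velocity is derived from a 2D
streamfunction ψ, so the flux carried between two streamlines equals their
ψ difference.  On the junction square ψ is a bilinear interpolation of the
four wall values (set by the caval/pulmonary fluxes) plus a
sin(πs)·sin(πt) bump whose amplitude is solved (Newton for the interior
saddle, Brent for the amplitude) so that the saddle — the stagnation point
where the four streams meet — sits exactly at the ψ level that assigns the
requested fraction of IVC flux (and hence of SVC flux) to the LPA.  The
junction patch is composed with a C² saturating map of each coordinate so
the limbs carry plug flow beyond 1.5 W and the global field is smooth.
Because the limb inflow is plug (uniform), uniformly seeded particles
sample flux uniformly, and the volume fraction of seeds on the LPA side of
the dividing streamline equals the flux split — which is what makes the
split a usable ground truth for particle counting.

Velocities are obtained by *discrete* central differencing of ψ sampled on
the grid: mixed central differences commute, so the discrete divergence of
the in-plane field is zero to machine precision (analytic differentiation
left a ~10⁻³ relative discrete divergence).  Geometry comparisons carry a
10⁻⁶ mm tolerance so wall-voxel inclusion is mirror-symmetric despite
floating point; without it the seeded emitter volume was asymmetric by one
voxel column and biased the recovered split by ≈ +0.04.

Pulsatility is a global factor 1 + p·sin(2πt/T) (default p = 0.3).  A
global scale factor leaves streamline geometry unchanged, so the flow
split is insensitive to it; physiologic waveform shapes and Womersley
profiles are out of scope and the sinusoid is a stand-in, not a claim of
fidelity.  Walls are slip (no boundary layer): limb plug flow has zero
interior shear, which makes the junction the dominant dissipation site —
convenient for testing, but unlike real vessels, where wall shear
contributes throughout.

Analytic oracle fields: uniform flow (zero dissipation, straight
pathlines), a Poiseuille tube v(r) = 2V̄(1 − r²/R²) with closed-form total
dissipation 8μLQ²/(πR⁴) and kinetic energy (2π/3)ρV̄²R²L, and solid-body
rotation v = ω×r (zero strain rate, circular orbits).  The Poiseuille
truth uses the *achieved* axial length of the discrete tube (occupied
slices × spacing) so it describes the phantom actually generated; the
in-plane discretization remains fully exposed to the test.

**Corruption model.**  Gaussian i.i.d. velocity noise, per-component
spatial polynomial offsets (order 1 or 2, world-mm basis) emulating
eddy-current/Maxwell phase errors, and venc aliasing
v → v − 2·venc·round(v/(2·venc)).  All randomness flows through one
explicit seed (default 20260928).

## Preprocessing

*Static tissue*: temporal SD of every component below a threshold
(default 0.01 m/s) and time-mean magnitude above 10% of the maximum
(excludes air).  *Phase offsets*: least-squares polynomial fit to the
time-averaged velocity over static voxels, subtracted everywhere — offsets
are treated as temporally static, which is why the fit uses the time
average.  *Anti-aliasing*: per component and frame, voxels differing from
their lumen-restricted 6-neighborhood median by more than venc are shifted
±2·venc toward the median, swept to a fixed point (cap 10).  This local
scheme resolves isolated or thin wrapped structures deterministically; a
large compact wrapped core whose neighborhoods are themselves wrapped is
not recoverable locally — a documented limitation shared by any
neighborhood vote.  *Noise masking*: velocity zeroed where time-mean
magnitude falls below the 5th percentile of the in-lumen distribution.
*PC-MRA*: time-mean of magnitude-weighted speed, with an Otsu threshold
utility for lumen segmentation.

## Geometry

Centerlines are minimal-cost paths over the 26-connected lumen voxel
graph with edge weights penalized by the inverse squared
distance-to-boundary, so the path follows the medial ridge while reaching
the user-supplied endpoints exactly (a pruned topological skeleton
retracts about one tube radius from open ends, corrupting arclengths and
end tangents).  Paths are smoothed with a window-5 moving average
(symmetrically shrinking at the ends, endpoints preserved) and resampled
at 1 mm arclength.  Analysis planes take the local tangent as normal and
cover the lumen cross-section plus a 2 mm margin.  The partition cuts the
lumen in a band of half the voxel diagonal around each plane (restricted
to the plane radius, so distant limbs are not severed), labels components
by their seed, and assigns band voxels to the proximal (connection) side —
a deliberately conservative connection region.

## Flow distribution

Emitters are seeded on a jittered cubic lattice at 30 per cm³ of source
region (stratification keeps the split estimator's sampling error near
0.006 at ~800 emitters, versus ~0.02 binomial).  Pathlines integrate
dx/dt = V(x, t) with classical RK4, trilinear spatial and linear periodic
temporal interpolation; dt defaults to one fifth of the frame duration and
the horizon to 3 cardiac cycles.  A trajectory ends on leaving the lumen,
on speed < 10⁻³ m/s for 5 straight steps, on first crossing a pulmonary
entrance plane, or at the horizon; each pathline is attributed to exactly
one artery (first crossing).  In the phantom region model the counting
planes sit two in-plane voxels distal of the junction, inside the straight
limb, so wall-hugging pathlines that cut the junction corner still cross
within the plane radius.  Emitters are released once at t = 0; per-frame
release is a non-goal and would change validity fractions, not splits, in
a steady-geometry phantom.  The recovered splits carry a residual
compression toward 0.5 of up to ~0.03 from wall-adjacent pathlines that
exit the staircase mask near the junction corners before reaching a plane.

## Voxel-wise maps

Scans are truncated to the minimum cardiac-cycle fraction covered (whole
frames, dropping late-cycle/end-diastolic frames), then resampled
trilinearly to 1 mm³ (labels nearest-neighbor).  Speed is the velocity
magnitude; "velocity < 0.1 m/s" for stasis is read as speed.  Gradients
for ϕ_v use central differences at interior lumen voxels and one-sided
differences at the boundary (three-point second-order where two in-mask
neighbors exist — exact for the quadratic Poiseuille profile — else
two-point), with out-of-mask neighbors excluded rather than zero-filled to
avoid spurious wall shear.  The ⅔(∇·V)δᵢⱼ compressibility term is retained
exactly as written even though measured fields are not divergence-free.
EL_tot integrates the EL rate by the midpoint rule in time (each frame
weighted by its duration — equivalent to a trapezoid on frame midtimes
with constant end extension), so EL_mean × covered duration ≡ EL_tot
identically, steady or not.  Regional peak velocity uses the 98th
percentile with linear interpolation between order statistics; KE is
summed over time per voxel and then averaged over the ROI (the plain
reading of the metric table).  At 1 mm the R = 8 mm Poiseuille tube's KE
is recovered to 0.01% and total EL rate to 3.9% (boundary staircase
dominates), both improving monotonically from 4 to 2 to 1 mm.

## Longitudinal statistics

Changes are annualized: (follow-up − baseline)/years, with the follow-up
interval required to exceed 0.5 years.  Rank-sum and signed-rank tests use
exact enumeration nulls whenever possible (n ≤ 10 per group / n ≤ 15
nonzero deltas, no ties) because the target cohort size (~10) makes
asymptotics dubious; otherwise the tie-corrected normal approximation.
Zero deltas are dropped before signed-ranking.  Spearman's rho uses
average ranks; its p-value is a two-sided permutation probability, exact
over all n! pairings for n ≤ 8 and 10⁵ seeded permutations (add-one
estimator) otherwise.  OLS provides slope, intercept, R² and the slope's
two-sided p.  Post-hoc power is Monte-Carlo with plug-in normal effect
models (two normals at the observed moments for rank-sum; one normal for
signed-rank; a bivariate normal at the observed rho for Spearman),
rejecting at α = 0.05 over ≥ 1000 simulations; inside power simulations
the Spearman permutation count drops to 2000, a granularity far below the
power estimate's own Monte-Carlo error.  No multiple-testing correction is
applied; the result table records how many tests were run.  The synthetic
cohort generator draws 10 subjects (5 with unequal baseline IVC flow
distribution), annualized peak-velocity drifts of 0.024 ± 0.066 (unequal)
vs 0.003 ± 0.038 m/s/yr (equal), and couples energy-loss changes linearly
to peak-velocity changes with noise sized to give R² ≈ 0.6 — it produces
realistic tables for the statistics stage, not simulated images.

## Numerical choices and degenerate inputs

Isotropic resampling covers the same world extent with trilinear
interpolation (exact on linear fields).  The dissipation mask must span at
least two voxels per axis.  Zero total plane crossings leave the flow
fractions undefined and flagged rather than silently zero.  The 30–70%
classification uses strict inequalities, so exactly 30% or 70% to the LPA
counts as equal.  All phantom randomness (noise, jitter, power
simulations) is reproducible from explicit integer seeds.

## Problem sizes

The default phantom grid is 47 × 55 × 15 voxels × 20 frames; acceptance
phantoms for energetics run at 4/2/1 mm on tubes of ~12 000 lumen voxels;
split recovery uses ~830 emitters per phantom; statistical calibration
uses 2000 simulated null datasets.  The full test suite runs in about half
a minute and the acceptance script in a few seconds on one CPU.

## Known limitations

Slip-walled plug limbs understate wall shear; the junction sinusoid is not
a physiologic waveform; the anti-aliasing sweep cannot recover large
compact wrapped cores; pathline losses at staircase corners compress
extreme splits slightly toward 0.5; the power model is a normal-theory
convention, so its absolute values are not comparable to power figures
computed under other models.  Passing phantom tests demonstrates the
correctness of the numerics and bookkeeping, not robustness to the full
artifact spectrum of clinical 4D flow data.
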