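# Methods

## Screw twists from poses

The relative motion of segment 2 with respect to segment 1 is given as
uniformly sampled homogeneous transforms `T_k`. The screw twist is extracted
with the spatial (left) difference convention, `ΔT = T_{k+1} T_k⁻¹`, so that
`(ω, v₀) = blocks of logm(ΔT)/Δt` are expressed in the reference coordinate
system and `v₀` is the velocity of the body point instantaneously at the
reference origin. This convention is what makes the ISA formulas
`n = ω/‖ω‖`, `S = ω×v₀/‖ω‖²` valid in reference coordinates. A body
(right) difference would yield the twist in moving-segment coordinates and
change `v₀` for recorded data; the spatial choice is fixed throughout.

The principal matrix logarithm is discontinuous at half-turn rotations;
consecutive-sample rotations with angle ≥ π − 1e-6 rad are rejected
(`BranchCutError`) rather than silently resolved to a branch. Twists are
stamped at pose-pair midpoints; this matters only for reporting, never for
estimation. All internal units are SI (m, rad, s); distances are reported in
mm and angles in degrees.

## ASA estimator

**Direction.** `C_ω = (1/N) Σ ωᵢωᵢᵀ` is deliberately *not* mean-centered:
its dominant eigenvector maximizes the mean squared projection `(ωᵢ·n)²`,
which weights every sample by its angular speed. Slow samples — exactly the
ones where the ISA direction is noise-dominated — contribute
proportionally little, so no angular-speed threshold is needed. The
eigenvector sign is aligned with the mean angular velocity (falling back to
largest-magnitude-component-positive when the mean vanishes) for
reproducibility.

**Position.** The damped normal equations
`(A + εI) S = b + εS₀` with `A = (1/N) Σ [ωᵢ]ₓ[ωᵢ]ₓᵀ`,
`b = (1/N) Σ [ωᵢ]ₓ v₀ᵢ` are solved directly (the identity
`[ω]ₓ[ω]ₓᵀ = ‖ω‖²I − ωωᵀ` is used to build `A` without forming skew
matrices). `ε` has units 1/s² and balances squared distance to the prior
(m²) against mean squared residual velocity (m²/s²); the default is 0.01,
kept small so the prior only resolves directions the data cannot. With
`ε = 0` and a condition number above 1e12 the minimum-norm (truncated
eigendecomposition) solution is returned together with a
`rank_deficient` flag and the null-space direction. For exact hinge data the
null direction *is* the rotation axis: the position is genuinely undefined
along it, the minimum-norm representative lies on the true axis, and
downstream reports state the distance to the unregularized position as
unbounded (`inf`) along that direction rather than inventing a finite
number from a singular solve.

**Frame.** ê₁ = n_asa; ê₂ = eigenvector of the smallest eigenvalue of
`C_ω`, i.e. the normal to the plane containing the largest ISA variation
(re-orthogonalized against ê₁ if floating-point drift exceeds 1e-9);
ê₃ = ê₁×ê₂; origin S_asa.

## Dispersion analysis

Confidence ellipsoids use `mᵢ = γ √λᵢ` with `γ = √(χ² quantile at α, 3 dof)`
(≈ 2.7955 at α = 0.95) — the square-root convention, which is the one
consistent with interpreting the ellipsoid as a population boundary of the
`ωᵢ` vectors. The residual variance `σ̂² = Σ‖ωᵢ×S_asa + v₀,ᵢ‖²/(N(3N−3))`
follows the regression estimate with `3N` observations, 3 parameters, and
the per-block `1/√N` scaling of the design matrix. The position covariance
is computed as `C_S = σ̂² (trace(C_ω)I − C_ω)⁻¹`, the closed form that
follows from the regression covariance via the skew-matrix identity; it
shares eigenvectors with `C_ω` and its dominant-uncertainty direction is
the ASA direction itself. For hinge-like data `trace(C_ω)I − C_ω` is
singular along the axis; the pseudo-inverse is used and flagged.

`σ̂²` conflates measurement noise with true ISA migration; the two are not
separable from velocity residuals alone, so ellipsoids quantify *total*
dispersion. The eigenvalue ratios ρ₁, ρ₂ are scale-free: ρ₁ → 0 for a
perfect hinge, ρ₂ distinguishes planar from isotropic residual variation.
When both eigenvalues entering a ratio are numerically zero the ratio is
reported as 0 (a ratio of rounding noise carries no information).

The conventional RMSE dispersion metrics (RMS ISA-vs-ASA angle; RMS
perpendicular distance from `S_asa` to each ISA line) are computed on the
threshold-filtered sample set (default 0.3 rad/s), since those metrics are
defined by the thresholded-literature procedure they summarize.

## Baseline ("SoA") estimator

The comparison baseline is the standard instantaneous-approach average:
ISAs of samples above the 0.3 rad/s threshold; direction = normalized mean
of sign-aligned unit ISA directions; position = unweighted least-squares
pseudo-intersection of the ISA lines (minimum-norm under rank deficiency).
Its contrasts with the main estimator — thresholding instead of velocity
weighting, unweighted lines instead of velocity-scaled residuals, no
regularization — are exactly the design differences under study.

## Synthetic motions

**Ideal cylindrical joint.** Swing angle `α(t) = A sin(2πt/T) + U` with
A = 45°, U = 180°, T = 1 s; the segment-2 origin rides a circle of radius
r = 0.25 m centered on the geometric axis (default `(0,0,1)` through
`(0,−0.25,0)` m); the segment's y-axis points at the rotation center, its
z-axis is the rotation axis. This makes the motion a pure rotation about
the geometric axis: every ISA coincides with it exactly, which is the
property the generator exists to provide (note that normalizing the full
origin vector instead of the radial offset would aim the y-axis at a point
*on* the circle and, by the inscribed-angle theorem, halve the rotation
rate and destroy the fixed-axis property). Sampling is 100 Hz over one
period, endpoint inclusive (101 poses / 100 twists) — a typical
optoelectronic capture of one swing cycle. With these choices the
first-axis orientation-ellipsoid magnitude of the reference motion is
9.753 rad/s (analytically `γ·π²/√8` plus a −0.02% finite-difference
factor).

**Hinge swing.** `θ(t) = A e^{−ζω₀t} sin(ω₀t)` about an arbitrary fixed
axis; default A = 45°, period 1 s, 100 Hz — matching the cylindrical
joint's velocity scale.

**Ball swing.** Rotation about a fixed center with the axis direction
sweeping a cone; gives full-rank pseudo-intersection problems for property
tests.

**Pose noise.** Each pose is right-multiplied by `exp` of an se(3) element
whose rotation vector has *fixed* magnitude (the stated level, e.g. 3°) and
uniformly random direction, independently per sample, and likewise for the
translation argument (e.g. 2 mm). Fixed-magnitude/random-direction makes
the quoted levels exact perturbation sizes rather than distribution scales.
Deterministic per seed.

What the generators do **not** emulate: soft-tissue artifact (correlated,
non-isotropic marker noise), marker-cluster pose reconstruction error
structure, non-uniform sampling, and fluoroscopy-specific anisotropy
(in-plane vs out-of-plane accuracy). Passing tests on these motions
demonstrate correctness of the estimators and their documented noise
response, not clinical accuracy on real recordings.

## Study protocols

*Regularization*: ASA at ε = 0 versus ε ∈ {1e-4, 1e-3, 1e-2, 1e-1}
(common-normal and position-point distance). *Sensitivity*: noise levels
(3°, 2 mm) and (6°, 4 mm), 100 repetitions, each method's noisy estimate
compared to its own clean estimate; SDs across repetitions; per-repetition
seeds spawned from a master seed (bit-identical reruns). *Dispersion*: the
full ellipsoid/ratio/RMSE report for one motion.

## Noise response and known limitations

Differencing fixed-magnitude pose noise at 100 Hz produces angular-velocity
noise of RMS `√2·δ/Δt` (≈ 7.4 rad/s for 3°), comparable to the signal for
1 Hz joint motion. Two consequences, measured with the package's own tools:

* Direction recovery from a *single* swing cycle under 3° noise is poor
  (~15° error); over a 10 s calibration-style trial it averages down to
  ~2–4°. Functional-axis trials should be several seconds long.
* Quadratic rectification of the rotation noise biases the *position*
  estimate toward the moving-segment origin by roughly 45% of the
  origin-to-axis lever arm at this noise level (e.g. ~20 mm for a 5 cm
  lever). The bias affects the threshold-based baseline at least as
  strongly (its repetition-to-repetition spread is larger, which is the
  sensitivity result), but it is not removed by the estimator; position
  accuracy under heavy pose noise therefore depends on mounting the
  marker cluster close to the joint axis.

Degenerate inputs are handled explicitly rather than numerically: all-zero
angular velocity raises (`UndefinedAxisError`), sub-threshold per-sample
ISAs carry a `defined = False` flag, rank-deficient solves return
minimum-norm solutions with flags and null directions, and eigenvector
signs are fixed by stated conventions so all outputs are reproducible
across runs and platforms.
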