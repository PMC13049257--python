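# Methods

`wfmra` implements a free-breathing, self-gated, retrospectively
motion-corrected, model-based water-fat reconstruction for dual-echo 3D
Cartesian MRA, together with the synthetic moving phantom used to validate
every stage against known ground truth.  This note records the models, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Signal model

Each k-space line is acquired at two echo times (TE = 2.8 / 6.5 ms) of a
spoiled gradient echo.  Water and fat are modeled as *real-valued* images
`w`, `f` sharing a common phase per echo:

    s_1 = (w + dfat_1 f) ∘ b_1
    s_2 = (w + dfat_2 f) ∘ b_2

`dfat_i = Σ_s α_s exp(2πj Δf_s TE_i)` is the complex fat evolution factor
(multi-peak spectrum with frequency shifts `Δf_s` and weights `α_s`); the
unit-modulus error phasors `b_1`, `b_2` absorb all phase the real-valued
model cannot express (B0 inhomogeneity, eddy currents, receive phase).  The
default constants `dfat = (0.70 − 0.37j, −0.58 − 0.20j)` are the calibrated
values for the default echo times; the `FatSpectralModel.peaks` field lets
the simulator evaluate `dfat` from an explicit peak list so data generation
and reconstruction stay self-consistent.  Note the calibrated constants are
used verbatim on the reconstruction side; no attempt is made to re-derive
them from a literature spectrum at 0.55 T, and a standard six-peak spectrum
evaluated at these echo times does not reproduce them exactly — the
discrepancy is inherited from the calibration, documented here, and not
resolved.

The real-valued formulation halves the number of unknowns per voxel relative
to a complex water/fat pair, removes the in/opposed-phase timing constraint
of classical two-point Dixon, and buys noise robustness; its price is the
global swap gauge discussed below.

## Sampling design

Phase-encode points are drawn as an overlay of three variable-density
Poisson-disk patterns with different seeds.  Each pattern fully samples the
central 5 % of the normalized radius
`r = sqrt((ky/ky_max)² + (kz/kz_max)²)` (half-grid maxima; corner cropping
keeps `r ≤ 1`), enforces a minimum peripheral density, and respects an
asymmetric partial-Fourier crop keeping the fraction 0.875 of each phase
axis on the positive side.  The density law is
`ρ(r) = A (1 − r)^p + ρ_min` with exponent `p = 2`; `A` is calibrated
analytically from the discrete area integral so the realized count lands
within ±2 % of the requested line budget.  Dart throwing with a
radius-dependent exclusion distance `δ(r) = s / sqrt(ρ(r))` (pairs compared
at their mean radius) realizes each pattern; the scale `s` is bisected over
a few seeded rounds until the target count is reached, and a per-annulus
top-up guarantees the peripheral floor.  All of this is deterministic under
the configured seeds.

For acquisition the points are split by normalized radius into
`nsegments − 1` equal-count bins (quantiles of the realized radii, which
guarantees schedulability, rather than theoretical annulus areas).  Each
heartbeat window acquires the ky=kz=0 self-navigator line first, then one
line per bin in center-out order.  When the point count does not divide
evenly, bins are exhausted as evenly as possible and only the trailing
window may be short.  The repeated center line gives one respiratory
sample per heartbeat at zero scan-time cost — this is what makes the scan
time exactly predictable.

The in-vivo protocol's printed total accelerations admit more than one
definition (full grid vs elliptical partial-Fourier region, point multiset
vs distinct points), so `verify_pattern` reports all four candidates rather
than asserting one.

## Self-gating and binning

The per-window center lines (echo 2 by default; configurable, since the
choice is not dictated by the model) are flattened over readout × coil with
real and imaginary parts stacked, centered across windows, and reduced to
their first principal component.  The score is lightly smoothed with a
smoothing spline (smoothing parameter 10⁻³ of the signal variance — the
spline step itself is required, its strength is a free choice) and
normalized to unit variance.  The surrogate is sign- and scale-ambiguous at
this point.

Windows are sorted by surrogate value and cut into `m = 4` contiguous
equal-count states (remainder spread one per group from the lowest group;
ties broken by window index for determinism).  Every window belongs to
exactly one state — no data sharing.  The end-expiratory reference state is
the extreme bin on the side of the surrogate's mode, since quiet breathing
dwells at end-expiration.

Once motion fields exist, the surrogate is calibrated to millimetres by a
line fit through (state centroid, mean foot-head diaphragm-ROI
displacement) pairs, signed so larger values mean inspiration.  The
reported respiratory range uses the per-window calibrated values, so
intra-bin excursions beyond the centroids are included.

## Respiratory-resolved reconstruction and motion fields

One second-echo image per state is reconstructed by minimizing

    Σ_m ‖P_m F C s_m − k_m‖² + λ_TV ‖∇_x s‖₁ + λ_TVT ‖∇_t s‖₁

with λ_TV = λ_TVT = 0.001 and 15 L-BFGS iterations.  The state-dimension TV
is what stabilizes the heavily undersampled per-bin problems; these images
exist only to drive registration and are never part of the final output.

Motion fields are estimated by an in-repo registration: regularized
multiscale optical flow (demons-style per-voxel updates along the local
intensity gradient, Gaussian-smoothed both in the update and cumulatively
in the field, over a three-level coarse-to-fine pyramid), after which the
dense displacement is projected onto a cubic B-spline control lattice with
a six-voxel pitch — a free-form deformation constrained over larger
regions, which keeps the warp smooth and avoids overfitting the residual
aliasing of the respiratory-resolved inputs.  The driving mismatch is the
sum of squared differences on peak-normalized magnitudes: all states come
out of one joint reconstruction, so their intensity scales agree.
Displacements are finally masked to a torso ROI with a Gaussian decay
(σ = 3 voxels) at the box boundary, so the final reconstruction sees no
motion-field edges and no spurious deformation of the static chest.  The
resulting fields recover 4-voxel translations with a mean endpoint error
below one voxel on the textured phantom, in seconds per state at the
default matrix.

Intra-bin refinement measures the foot-head displacement difference between
adjacent states in a small liver-dome ROI, scales it by the
hepatic-to-cardiac motion ratio 0.57, and — wherever the result `Δms`
exceeds one voxel — inserts `round(Δms/2)` intermediate states (round half
up, the minimal completion of the half-count rule) whose fields and
surrogate centroids are linear interpolations of the neighbours.  Windows
are then re-assigned to the nearest centroid.

The warp operator is trilinear resampling with precomputed stencils; its
adjoint is the exact transpose of the interpolation matrix, *not* the
inverse warp.  Exact transposition is what lets the motion-compensated
encoding chains pass randomized inner-product adjoint tests at 10⁻¹⁰
relative error, which in turn is what makes the model-based gradients
trustworthy.

## Motion-compensated echo reconstruction and image-based Dixon

Both echo images are reconstructed by conjugate gradients on the normal
equations of the motion-compensated SENSE operator
`E_moco,m = P_m F T_m C` (warp acting on the coil-weighted image, matching
the encoding definition; 10 iterations).  The data residual is monotone by
the CG energy-norm identity and is recorded per iteration.

The per-voxel two-point system (4 real unknowns `w, f, φ1, φ2` against 4
real measurements) is solved in closed form: eliminating `w²` from the two
magnitude equations leaves a quadratic in `f²` whose two roots are the true
and the swapped interpretation.  Numerical care: the stable quadratic form
avoids cancellation, a signed-sqrt expression for `w` avoids dividing by a
vanishing `f`, and two vectorized Newton steps polish both roots to machine
precision.  `w` and `f` are proton-density magnitudes, so the candidates
are clamped to the nonnegative branch; the sign that clamping discards is
pure gauge where either component vanishes and is exactly the degree of
freedom the error phasors absorb.

The per-voxel true/swapped labeling is resolved by spatial smoothness of
the inter-echo phasor `q = b_2 conj(b_1)`: confidence-seeded region growing
(seeded at the brightest voxel, neighbours labeled to match the grower's
`q`) followed by iterated-conditional-modes sweeps against the local mean
`q`.  Voxels with no signal in both echoes are gauge-fixed to
`w = f = 0, b = 1`.  Two-point real-valued Dixon is identifiable only up to
a *global* swap; outputs follow the convention that the volume-integrated
water signal exceeds the fat signal, and tests compare up to this gauge.

`b_1` is then smoothed as a complex field with a truncated Gaussian
(σ = 1.0 voxel, radius 4 voxels), renormalized to unit modulus; `b_2` is
rebuilt as smoothed-`b_1` times the original voxelwise `q`, preserving the
inter-echo difference exactly.  Voxels where the smoothed phasor cancels
(phase singularities) keep their original value.

## Model-based water-fat reconstruction

The final stage minimizes

    Σ_i Σ_m ‖E_m,i(w, f) − k_m,i‖² + λ_TV,w ‖∇_x w‖₁ + λ_TV,f ‖∇_x f‖₁

over real `(w, f)` with λ_TV,w = λ_TV,f = 0.0007 and 10 L-BFGS iterations,
warm-started from the image-based result; the motion fields `T` and
phasors `B` stay fixed throughout.  The adjoint of the water-fat encoding
takes the real parts of the `conj(b_i)`- and `conj(dfat_i b_i)`-weighted
back-projections — the exact adjoint of embedding real images in complex
space, verified against central finite differences at 10⁻⁵ relative.
The encoding of the fat pathway uses the same per-echo
motion/mask/Fourier chain as the water pathway; echo dependence enters only
through `b_i` and `dfat_i`.

All nonsmooth `‖·‖₁` TV terms are smoothed as Charbonnier penalties
`sqrt(|d|² + ε²) − ε` with `ε = 10⁻⁶ ×` the initializer's dynamic range, so
the L-BFGS solver (memory 10, strong-Wolfe line search via SciPy's
L-BFGS-B) sees a differentiable objective; iteration counts are the only
solver parameters fixed by the protocol, and solvers stop early on
insufficient objective decrease.

## Navigator-gating simulation

The comparison arm accepts a heartbeat iff the diaphragm position lies
within ±4 mm of the end-expiratory reference (one instantaneous navigator
event per beat), and the scan runs until the line budget is collected.  The
reference is either given or "learned" as the histogram mode of the first
20 s (quiet breathing dwells at end-expiration, so the mode sits there; how
the scanner sets this reference in practice is not modeled further).  The
self-gated acquisition accepts every beat, so its scan time equals the
nominal time identically; the simulator quantifies how irregular breathing
inflates the scan-time variance of the gated arm.  The navigator's
image-space saturation artifact is out of scope — its appearance is
anatomy-dependent and has no desk-scale ground truth.

## The synthetic phantom and what passing tests mean

The phantom is a thorax-scale caricature: an elliptical water body with a
peripheral fat layer, a brighter liver below a curved diaphragm interface,
a heart ellipsoid, and thin (≤ 3-voxel) water-only tubes along the
foot-head axis probing vessel sharpness.  A smooth ±18 % parenchymal
texture is superimposed — a piecewise-constant interior would leave
interior registration control points unconstrained, which no real tissue
does.  Phase fields come from one smooth synthetic off-resonance map
(±30 Hz) plus a smooth receive phase; coil maps are four smooth complex
lobes around the perimeter.

Motion is a foot-head translation of the sub-diaphragm compartment with a
linear decay to zero at the chest apex and the heart moving at 0.57× the
diaphragm — analytically known, so ground-truth warps can be injected to
decouple registration error from reconstruction error.  Breathing traces
are raised-cosine cycles with an expiratory plateau (exponent 1.6),
rescaled to span exactly ±A; irregular mode jitters per-cycle amplitude,
period and end-expiratory baseline, drifting mode adds a monotone baseline
drift.  The default period is 3.8 s (≈ 16 breaths/min): a period
commensurate with the 1 s heartbeat would phase-lock the sampled trace onto
a handful of positions, which no physiological recording shows.

Default study conditions: 64 × 64 × 32 grid at 3 mm, 96 heartbeat windows
of 16 lines (≈ 1.4-fold line coverage of the elliptical partial-Fourier
region, i.e. ≈ 5.5-fold per motion state), 12 mm peak-to-peak motion
(4 voxels), complex k-space noise at 3 % of the peak coil-weighted signal
(between the noiseless operator checks and the 20 dB-SNR gating stress
case).  The full in-vivo-scale matrix is config-reachable but not exercised by the
tests.

What the phantom does *not* emulate: realistic anatomy, flow and pulsatile
effects, intra-window (cardiac) motion, eddy-current phase beyond the
smooth synthetic fields, coil compression/noise correlation, and the
navigator saturation artifact.  Passing tests therefore demonstrate the
correctness and internal consistency of the pipeline — operators, solvers,
separation, gating logic — under smooth-phase, translation-dominated
motion; they do not certify in-vivo image quality.

## Degenerate inputs and tie-breaks

Zero-variance center lines yield a flagged constant surrogate; binning ties
are broken by window index; all-zero motion fields make the mm calibration
unidentifiable and raise; empty state masks, mismatched schedule/trace
lengths and non-finite fields are rejected with messages naming the
offender; CG returns its last good iterate with a warning if the residual
ever increases; registration failures fall back to a zero field with a
warning rather than aborting the pipeline.

## Known limitations

Registration-based fields are the dominant error source at desk scale
(mean endpoint error ≈ 0.1–0.4 voxel on clean state images and ≈ 1 voxel on
the artifact-laden respiratory-resolved states, where structured per-state
undersampling also biases apparent positions by 1–3 mm, diluting the
whole-volume benefit of registered-field motion correction); `B` and
`T` are never updated during the final iterations; partial-Fourier
truncation is handled implicitly by the real-valued model rather than by
homodyne completion; fat estimates are noisier than water by the two-point
conditioning; and the graph-cut labeling of the reference Dixon literature
is replaced by region growing + ICM, which can in principle lock onto a
wrong basin on phase fields far rougher than the smoothing scale.
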