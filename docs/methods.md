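# Methods

This package simulates capacitively coupled electrical impedance tomography
(CC-EIT) of the human thorax with a wearable 32-electrode belt, and studies
how electrode displacement — inevitable with an elastic band strapped onto a
chest — affects neural-network image reconstruction.  Everything is
synthetic: scenes, fields, measurements and training data are generated by
the package itself.

## Electrode displacement model (`cceit.band`)

Three displacement sources compose additively in angle, in the order
stretch → global rotation → local jitter:

1. **Band stretch.**  Normalized arc-length positions along the band are
   remapped by a function `f: [0,1] → [0,1]` with `f(0)=0`, `f(1)=1`,
   strictly increasing (electrodes can slide but not swap).  The family is a
   two-term rotated-sine curve, parametrized by `(a1, b1, a2, b2)`:

       x3(t) = t − S2(t),   y3(t) = t + S2(t),
       S2(t) = a1 (sin(πt + b1) + (2t−1) sin b1) + a2 (sin(2πt + b2) − sin b2),

   with `f = y3 ∘ x3⁻¹`.  The curve is a bijection iff `|S2′(t)| < 1` on
   [0,1]; a conservative sufficient box is `|a1| ≤ 1/(2(π+1)) ≈ 0.1207`,
   `|a2| ≤ 1/(4(π+1)) ≈ 0.0604`, any phases.  Sampling draws amplitudes
   uniformly in the box and phases uniformly in [0, 2π].  `x3⁻¹` is
   evaluated by bisection (robust; monotone by construction) to 1e−12.
   The derivative scan (dense grid, ≥10⁴ points) is the operative
   admissibility test; the box only bounds the sampler, and parameter sets
   outside the box can still be admissible.

2. **Global rotation** `g` and 3. **local jitter** `l_i`: truncated-normal
   draws (zero mean, hard-truncated at ±1 SD, rejection sampling) expressed
   in percent of the inter-electrode pitch 2π/32 = 11.25°.  The
   disarrangement levels are (local SD, global SD) = (0,0) `none`,
   (2.5, 7.5) `small`, (5.0, 12.5) `medium`, (10.0, 50.0) `large`; `none`
   also disables the stretch.  Note that the stretch amplitudes do **not**
   scale with level — all displaced levels share the full admissible box —
   so the level ordering is carried by the jitter and rotation terms on top
   of a common, often dominant, stretch perturbation.

Electrode `i` (of 32) sits at rigid normalized position `i/31`; the stretch
maps that across the band's angular span of 31 pitches, anchoring the first
and last electrode and leaving the closure gap unstretched.  Electrode arcs
cover 50% of the pitch: with the spec'd-family stretch amplitudes, wider
arcs (e.g. 80%) overlap for most level=large draws — a measured 90% failure
rate — because adjacent spacing contracts by the factor
`f′ = (1+S2′)/(1−S2′)`.  When arcs overlap, local jitter is re-drawn (up to
100 times); if the stretch itself packs electrodes below the arc width, the
stretch and rotation draws are re-drawn too (up to 100 outer retries).

## Thorax phantom (`cceit.phantom`)

A transversal slice: elliptical body outline containing two lungs, heart,
aorta and spine as ellipses, positioned to visually match a supine CT-derived
layout; exact template coordinates live in `phantom._TEMPLATE` and are
config-editable, since no canonical numeric anatomy exists for this phantom.
Randomization jitters each organ's center (uniform ±0.05 FOV units),
semi-axes (uniform ±10%) and rotation (±0.1 rad); draws repeat up to 100
times while any organ pair overlaps (256-point boundary sampling test) or an
organ leaves the body, after which the sample is rejected — rejection stays
below about 1% at these defaults.

Pathologies are assigned per lung, independently: pneumothorax with p = 1/2
and effusion with p = 1/2, making healthy / pneumothorax / effusion /
hydropneumothorax equiprobable at 25%.  Pneumothorax is painted as an
anterior pleural crescent of air (the lung ellipse minus an inner ellipse
shifted posteriorly; air rises in the supine position), effusion as a
posterior crescent of fluid.  Crescent shape parameters (0.88 axis scale,
0.30 posterior shift) are visual choices.

Tissue properties at the 100 MHz excitation frequency come from the standard
dielectric-property literature (relative permittivity / conductivity S/m):
background soft tissue 66/0.71, inflated lung 31.6/0.38, heart 90.8/0.73,
aorta (blood) 76.8/1.23, spine (cortical bone) 15.3/0.064, air 1/0, pleural
fluid 70/1.5.  Complex permittivity is assembled as ε = ε′ + jσ/(ωε₀) in
relative units.  Rasterization is pixel-center point sampling (no
anti-aliasing) on a 64×64 image grid; row 0 is anterior.

## Forward model (`cceit.forward`)

The band sits on the skin, so the body outline doubles as the sensor
boundary: outline-adjacent grid cells are Dirichlet (electrode arcs at the
layout's angles carry the excitation voltage U = 1 V; everything else is
screen at 0 V), and `∇·(ε∇φ) = 0` is discretized by a cell-centered finite
volume scheme with harmonic-mean face permittivities — the flux-conserving
choice for discontinuous coefficients.  One sparse LU factorization per
permittivity serves all 32 excitations.  Verification: the annulus geometry
(inner conductor at U inside a grounded ring, uniform ε) reproduces the
analytic log-radial potential to 0.4% at 128×128 when compared at the
staircase boundary's effective conductor radii (mean radius of the exposed
Dirichlet cells); comparing at nominal radii adds an O(h) geometry bias
unrelated to solver accuracy.

The sensitivity matrix follows from reciprocity:
`∂C_AB/∂ε_n = −(1/U²) Σ_{cells∈pixel n} ∇φ_A·∇φ_B Ω_cell`, with
central-difference gradients (one-sided at the boundary) and solver cells
aggregated into image pixels.  `S` is computed at the uniform background
reference — where the field equation is homogeneous in ε, so the solve is
real and reference-value-free — and measurements use the linear model
`C = S ε` (992 ordered excitation/sensing pairs; reciprocal entries equal by
construction).  Against brute-force finite differences of the direct
energy-form capacitance `C_AB = −(1/U²) Σ_faces w_f Δφ_A Δφ_B` on an
8-electrode 32×32 toy sensor, the sensitivity rows agree within 10%
(median ~1.5%).  The default solver grid is 64×64 with 1×1 cell→pixel
aggregation; a per-sample sensitivity matrix then costs ~0.15 s, which is
what makes per-layout S feasible for every displaced sample on one CPU.
A 128×128 solver with 2×2 aggregation is a config switch away.

A Landweber iteration (`x ← x + α Sᵀ(C − Sx)`, step inside the convergence
bound, optional non-negativity clamp) is included purely as a deterministic
sanity-check baseline for the forward stack; it is not a study method.

## Datasets (`cceit.dataset`)

Measurements are normalized by the two-reference ECT scheme — per-channel
affine map `(C − C_low)/(C_high − C_low)` with references simulated from
uniform air and uniform background-tissue scenes — computed in the complex
plane and projected to the real part, which keeps normalization exactly
linear in the permittivity vector (a midpoint scene lands on 0.5
everywhere).  References are always simulated from the *nominal rigid*
sensor: a wearable system cannot acquire calibration measurements with the
patient's actual band placement, so displacement must perturb the normalized
input rather than being calibrated away.  (Normalizing each sample with its
own displaced layout's references — our first implementation — cancels most
of the displacement signal and flattens the robustness effect.)

Gaussian noise is added to the normalized vectors, one σ per sample:
σ = |C_opp| / 10^(SNR/20) with SNR = 30 dB and |C_opp| the mean absolute
value over the 32 diametrically-opposite channels, which carry the smallest
raw capacitances.  Channels are noised identically, so larger channels see
higher SNR on average; the per-channel floor is not strict, because a
heterogeneous thorax spreads the opposite-pair magnitudes well below their
mean.  Noise never touches images.

Containers are single HDF5 files (`/images`, `/measurements`, `/labels`,
`/layouts` JSON, `/seeds`), gzip-chunked, written with `track_times=False`
so identical builds are bit-identical.  Dataset builds are deterministic
under the spec seed via per-sample spawned child seeds.

## Reconstructor (`cceit.recon`, `cceit.nn`)

The generator maps the 992-vector to 64×64: a learned affine projection to a
64×64 plane, six conv blocks (4×4 stride-2, batch-norm except the first,
leaky-ReLU 0.2) down to 1×1, six deconv blocks (4×4 stride-2 transposed
conv, batch-norm, 50% dropout on the first three, leaky-ReLU) back up with
U-Net skip concatenations, then a 3×3 convolution to one channel (linear
output).  Channel widths are (1×, 2×, 4×, 8×, 8×, 8×) a base width (64 at
full scale).  Dropout stays active at inference, replacing the latent noise
vector of a classic conditional GAN; inference is deterministic given
weights and a dropout seed.  The discriminator conditions on the
measurements by projecting them to a second 64×64 plane concatenated with
the image, followed by three conv blocks, an extra stride-1 conv block, and
a stride-1 conv + sigmoid producing patch probabilities in (0,1).

Training alternates a generator step (discriminator frozen, BCE target 1,
plus 100·L1 + 100·L2 against ground truth) and a discriminator step
(generator frozen; fake→0, real→1, the two BCE terms averaged).  Both
optimizers are Adam (β₁ = 0.5, β₂ = 0.999, coupled L2 weight decay 0.1)
with starting learning rates 10⁻³ (generator) and 10⁻⁶ (discriminator), and
cosine-annealing warm restarts (T₀ = 1000 iterations, T_mult = 2) stepped
per iteration.  Early stopping monitors the full generator loss on a
validation split (batch-statistics forward, dropout reseeded each
evaluation so values are comparable): training stops after `patience`
consecutive epochs without a relative improvement above 10⁻³, capped at 150
epochs, and the lowest-validation-loss weights are restored.  "No
significant change", the monitored quantity, and the dropout placement are
all underdetermined choices; each is configurable.

All layers are NumPy with hand-written backpropagation (im2col/col2im
convolutions); analytic gradients are verified against central finite
differences layer-by-layer and end-to-end in the test suite.

## Metrics (`cceit.metrics`)

SSIM (scikit-image reference implementation: 11×11 Gaussian window,
σ = 1.5, standard stabilizers), PSNR, RMSE and the 2D Pearson correlation.
RMSE/PSNR are reported on 8-bit-scaled intensities: both stacks are min-max
scaled to 0–255 using the ground-truth stack's bounds, the only scale on
which an RMSE near 8 and a PSNR near 29 dB are mutually consistent.  The
evaluation grid reports mean ± SD of each metric for every (training level,
test level) combination.

## Problem sizes

The full-scale study uses ~150k thorax + ~49k ellipse training samples per
level, ~20k-sample test sets, base width 64 and up to 150 epochs.  The
package's default experiment (`cceit.experiments.run_robustness`) is
desk-scale: 384 training samples per level (75% thorax / 25% random
ellipses, mirroring the full composition), 48-sample test sets per level,
solver grid 64×64, base width 8, batch 16, 10 epochs.  These sizes were
fixed once, as the smallest configuration where adversarial training is
still meaningful on one CPU core; they are not tuned per run.  Desk-scale
reconstructions are blurry (SSIM far below the full-scale regime), so the
robustness experiment is read qualitatively — ordering of means — not as a
reproduction of full-scale metric values.

## Known limitations

* The linearized forward model `C = S(ε − ε_ref) + C_ref` ignores the
  nonlinearity of the field equation in ε; the package never re-solves
  fields per sample beyond the per-layout sensitivity computation.
* Electrode arcs are angular intervals, exact only for circular outlines;
  on the elliptical body they approximate equal-arc-length pads.
* 2D only: no out-of-plane currents, respiratory motion, or per-patient
  thorax perimeter variation; no electrode–skin contact model.
* Tissue dielectric values are literature constants, not subject-specific.
* The stretch family is a geometric surrogate, deliberately broader than
  elastic-rod physics; it does not conserve band length.
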