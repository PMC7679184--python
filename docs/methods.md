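# Methods

This note documents the models, conventions and numerical choices behind
`phaseret`, and what its synthetic experiments do and do not demonstrate.

## Wavefront model

An aberration is described by its optical-path deviation φ(kx, ky), in µm,
on the objective's back pupil, expanded in Noll-indexed Zernike modes:

    φ(kx, ky) = Σᵢ aᵢ Zᵢ(kx, ky)

All modes carry the **unit-RMS (Noll) normalization**: the disk average of
Zᵢ² is 1, so each coefficient aᵢ equals the RMS wavefront contribution of
its mode and the total wavefront RMS is √(Σ aᵢ²). This convention is what
makes the amplitude-space error √(Σ Δaᵢ²) and the pupil-sampled wavefront
RMSE interchangeable (the package verifies the identity to 1% on a 128²
grid), and it is the convention under which 11 modes drawn uniformly from
±0.075 µm produce input wavefronts of median RMS 0.14 µm. Peak-to-valley
normalization would not reproduce that relation, which is why unit-RMS is
the only self-consistent reading; it is nevertheless a convention choice and
is flagged as such here.

The default regression target is Noll 5–15, the first 11 non-trivial modes.
Piston, tip, tilt and defocus are excluded: they encode bead position and
focus, not aberration. Within 5–15 the even-azimuthal-parity class is
{5, 6, 11, 12, 13, 14, 15} and the odd class {7, 8, 9, 10}.

Pupil sampling: the pupil disk is the *strict* inequality kx² + ky² <
(NA/λ)², sampled at voxel centers with no edge anti-aliasing; DC sits at
sample ⌊N/2⌋ so masks are point-symmetric for even and odd N alike.
Decomposition is ordinary least squares on the masked samples (minimum-norm
on rank deficiency).

## Image formation

Each defocus plane of the intensity PSF is the squared modulus of the 2D
Fourier transform of the pupil field

    h(x, y, z) = |F[P · exp(2πi φ/λ) · exp(−2πi z √(n0²/λ² − kx² − ky²))]|²

with P the binary pupil and n0 the immersion index. The model is scalar —
no vectorial high-NA corrections, no index-mismatch depth aberration, no
pupil amplitude attenuation. NA < n0 is enforced so the axial root is real.

Numerics:

- **Padded simulation grid.** The FFT runs on a grid `oversample_factor ×
  max(nx, ny)` per side (default 2) and the result is center-cropped, which
  pushes FFT wrap-around outside the crop. Pre-crop, per-plane energy is
  conserved exactly (Parseval); the FFT path matches a direct matrix-DFT
  evaluation of the Fourier sum to 1e-10 relative.
- **Focus convention.** z = 0 at the stack center; planes are spaced by the
  axial voxel and, for even nz, straddle focus symmetrically. Stacks are
  indexed (z, y, x), plane 0 at the most negative z.
- **Normalization.** Stacks are scaled so the unaberrated in-focus peak is
  1; the peak of an aberrated stack is then its Strehl ratio.
- **Bead.** Finite bead size is a 3D convolution with a unit-sum voxelized
  solid sphere; a voxel belongs to the sphere if its center is inside the
  radius, with optional sub-voxel supersampling (used ×3 when the bead
  spans more than ~1.5 lateral voxels, e.g. the 200 nm widefield bead).
- **Noise.** The stack is scaled to an expected peak photon count
  (default 300), Poisson counts are drawn per voxel, zero-mean Gaussian
  read noise with σ = 2% of peak is added, the result is rescaled and
  clipped at 0. The defaults visibly perturb the side lobes without
  destroying them and are exposed in the config.
- **Network input.** Every stack is standardized per volume to zero mean
  and unit variance, making predictions invariant to acquisition gain and
  offset.

Two shipped configurations: `point_scanning` (NA 1.4 oil n0 = 1.518,
λ = 0.755 µm, 32³ at 30 nm isotropic, 80 nm bead) and `widefield` (NA 1.1
water n0 = 1.33, λ = 0.488 µm, 50³ at 86/100 nm, 200 nm bead). The
widefield immersion index is taken as 1.33 (water). A third,
`point_scanning_small` (16³ at 60 nm isotropic, same optics), supports
CPU-scale training demonstrations; the coarser voxel keeps roughly the same
physical field of view at an eighth of the data volume while remaining
beyond Nyquist for the intensity spectrum.

## PhaseNet

Five blocks of two 3×3×3 same-padded convolutions (stride 1, channels
doubling from 8), each followed by a factor-2 max-pool; then dense layers
64–64–n with tanh activations everywhere except the linear output. For a
32³ input and 11 outputs this is 896,851 ≈ 0.9 M trainable parameters.

**Pooling axes.** A description of the architecture as pooling "only along
the lateral dimensions" is incompatible with both a 32³ input surviving
five poolings laterally (32/2⁵ = 1, so a sixth of anything is impossible —
but more to the point, the flattened 1×1×32×128 tensor would make the first
dense layer alone larger than the total printed above). Pooled axes are
therefore configurable per block; the default schedule pools every axis
whose extent is still even, which for 32³ pools all three axes in every
block and reproduces the 0.9 M total. Explicit schedules are validated
against the divisibility contract and reject non-divisible extents by name.

**Backend.** The network is implemented directly on NumPy in float32:
im2col convolutions, hand-derived backpropagation (verified against finite
differences in the test suite) and Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-7).
Glorot-uniform initialization, seeded. Checkpoints are .npz weight archives
with a JSON sidecar carrying the architecture spec and the training
config, so `predict` can refuse stacks whose shape or voxel sizes do not
match the training setup — silent resampling is never attempted.

**Training.** Pairs are streamed, never materialized: amplitudes uniform on
±0.075 µm per mode, fresh PSF per pair, so no example repeats and
overfitting in the classical sense cannot occur. The loss is the MSE
between predicted and true amplitudes (µm²). The reference recipe is
50,000 steps at batch size 2 and learning rate 1e-4 (roughly a day of
compute at the 32³ scale); the package's own experiments use the reduced
recipe — 16³ input, base 4 channels, 2000 steps at batch 8 — which reaches
a median validation wavefront RMSE of ~0.06 µm against 0.14 µm inputs in a
few minutes on one CPU. Validation sets are frozen with a dedicated seed
(default 200 pairs) and drawn from the same distribution as training.

## Gerchberg–Saxton baseline

Parallel multi-plane alternating projections: propagate the unit-amplitude
pupil estimate to every plane with the defocus kernel, replace each plane's
modulus by √(measured intensity) keeping phase, back-propagate, average the
per-plane pupil fields, re-impose the support/unit-amplitude constraint;
30 iterations by default, deterministic zero-phase start (seeded random
restarts optional). Implementation choices that matter:

- **Image-space padding.** A 32-pixel bead crop at 30 nm samples the pupil
  with only ~1.8 samples of radius — far too coarse to fit 15 modes. The
  measured planes are therefore embedded in a zero-padded grid (auto-chosen
  power of two giving the pupil ≥ 3 samples of radius) and the modulus
  constraint is enforced only inside the measured window, leaving the model
  amplitude free outside. Heavier padding enlarges that unconstrained
  region and was found to help neither accuracy nor noise robustness.
- **Per-plane scale matching** makes the retrieval independent of
  acquisition gain.
- **Trivial-mode removal.** The retrieved phase is projected onto Zernike
  modes, the least-squares piston/tip/tilt/defocus component (bead
  mis-centering) subtracted, and modes 5–15 reported.
- **No unwrapping.** At the amplitude ranges targeted here |φ| stays well
  below λ/2, so the pupil phase never wraps; a wrap detector (neighbor
  jumps > 0.6λ on the twice-eroded mask, the erosion discarding
  noise-dominated edge samples) raises instead of silently unwrapping.

On noiseless single-mode stacks GS recovers the truth to < 0.01 µm RMSE;
on noisy mixed-mode widefield stacks its median error is several-fold worse
than the trained network's, the gap that motivates the learned approach.
The exact plane-ordering/relaxation variant of other GS implementations is
not reproduced, so their published numbers on experimental data are not
comparison targets for this implementation.

## Plane-count experiments

`plane_subset_experiment` trains a fresh reduced network for every
(nz, mode-class) combination on stacks of nz contiguous planes centered on
focus at the native z step, then scores a frozen validation set. The
mechanism it probes is exact in the forward model: flipping the sign of a
purely even-parity aberration mirrors the 3D PSF axially and leaves the
z = 0 plane unchanged (verified to 1e-6 relative), so a single-plane
network can at best learn |a| for even modes — the true-vs-predicted
correlation sits near 0 at nz = 1 and jumps above 0.9 once a second plane
breaks the symmetry. Odd modes point-reflect laterally under sign flips and
are recoverable from one plane. Default experiment scale: single modes
(a5 even, a7 odd), 800 steps, 60 validation pairs — enough for the effect
to be unambiguous on one CPU in ~2 minutes.

## What the synthetic experiments show — and don't

All training and evaluation here runs on data from the package's own
forward model. That makes the tests a check of *inverse-problem learning*:
the network demonstrably inverts the image-formation physics from
simulations alone, the mechanism the approach relies on. It does not
exercise the sim-to-real gap — experimental PSFs carry background
structure, depth-dependent aberrations, vectorial effects at high NA and
camera artifacts the scalar model omits. Transfer to a real microscope
requires matching the configuration to the instrument and accepting the
scalar-model approximation; discontinuous wavefronts (phase ramps, double
helix) are outside the low-order Zernike representation entirely.

## Degenerate inputs and tie-breaks

- Empty or sub-mode-count pupil masks raise; the DC sample is always inside
  the mask, so a valid grid has ≥ 1 sample.
- Bead diameter 0 (and beads smaller than half a voxel) are a point
  emitter: identity convolution.
- Noise with zero photon rate and zero σ is the identity; negative
  intensities entering GS are clipped at 0 before the square root.
- All stochastic components (amplitude draws, noise, weight init, restart
  phases) take NumPy `Generator` seeds; every experiment in the tests and
  scripts is reproducible bit-for-bit on a given BLAS.
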