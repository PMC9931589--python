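# Methods

## Self-supervised training model

The denoiser assumes that two temporally adjacent frames of a fluorescence
time-lapse stack are two noisy observations of (nearly) the same underlying
signal, with independent detection noise.  A block of 2·s consecutive frames
is deinterleaved into an even-index input substream and an odd-index target
substream (parity fixed: even→input, odd→target; a random input/target swap
with probability ½ during augmentation makes the choice statistically
immaterial).  Minimising the composite loss

    L(p, y) = ½·( mean|p − y| + mean(p − y)² )

over such pairs trains the network toward the conditional expectation of the
signal.  Both loss terms are per-voxel means, so the ½-weighted combination
is scale-consistent across patch sizes.  The gradient of the L1 term uses
sign(r), with sign(0) = 0.

Validity rests on the slow-dynamics precondition: the signal must change
little over one frame interval.  For the synthetic default conditions the
clean frame-to-frame Pearson correlation exceeds 0.99 (tested); recordings
whose dynamics approach the frame rate violate the assumption and are
outside the method's domain.

Preprocessing subtracts the whole-stack mean (restored after inference).
For volumetric sessions every plane contributes pairs to a single model; the
restoring mean is the average of the per-plane means.

## Network

An all-3D encoder–decoder with four resolution levels.  Hidden widths are
(16, 32, 64, 128) scaled by a width multiplier; encoder blocks are
conv(in→w/2)+conv(w/2→w), decoder blocks conv(concat→w)+conv(w→w) after
trilinear ×2 upsampling and skip concatenation, all kernels 3×3×3
same-padded, 2×2×2 max pooling, LeakyReLU(0.1) activations, no
normalisation layers, and a final 1×1×1 projection.  This schedule was
reconstructed from the two published totals, which it reproduces exactly:
multiplier 1 → 1,020,337 trainable scalars, multiplier 4 → 16,315,585
(ratio ≈ 16: hidden-to-hidden convolutions scale quadratically with the
multiplier, the two boundary convolutions linearly).  Input extents must be
divisible by 8; `predict` reflect-pads to the next multiple and crops, so
the default 150³ patch is handled transparently.

The engine (im2col convolutions, pooling, interpolation, Adam, backprop) is
written directly on numpy in float32.  Upsampling is applied as a per-axis
interpolation matrix so its adjoint is exactly the transpose; convolution
gradients were validated against finite differences and the forward pass
against `scipy.ndimage.correlate`.

## Optimisation

Adam with moment decays (0.5, 0.9).  The full-scale configuration
(`TrainConfig` defaults) is learning rate 5×10⁻⁵, 150³ patches, 3,000 pairs,
20 epochs, batch size 1, last-epoch selection, no schedule and no early
stopping.  Pair origins are fixed at extraction; every epoch re-draws each
pair's augmentation form from the seeded stream (fresh re-augmentation
maximises the value of the 12-fold group).  Temporal block starts are evenly
spaced so any requested pair count fits the stack; spatial origins are
uniform with the seed.

The scaled CPU benchmark preset — quarter-width model, 32³ patches, 150
pairs × 2 epochs (300 steps) — uses learning rate 1×10⁻³, the conventional
Adam step size for small networks; 5×10⁻⁵ is tied to the full-size
multi-thousand-step regime and would barely move a small model in 300 steps.

## Augmentation group

{keep, swap input/target} × {identity, horizontal flip, vertical flip, left
90°, 180°, right 90°} in the x-y plane = 12 equiprobable forms, the same
geometric transform applied jointly to input and target (joint application
preserves their correlation; tested).  For non-square x-y patches the two
90° rotations would change the shape, so the draw restricts to the 8
shape-preserving forms with a logged warning; default patches are square and
always use all 12.

## Tiling and stitching

Windows start at 0, stride, 2·stride, … with stride = round(p·(1−overlap));
the final start is clamped flush to the boundary and duplicates are removed.
This reproduces the published benchmark arithmetic: a 490×490×300 stack with
150³ patches at 40% overlap gives 5×5×3 = 75 windows and 253,125,000 voxels
through the network.  Stitching keeps only the central region of each patch:
the cut between neighbouring windows sits at the midpoint of their overlap
(the earlier window keeps the extra voxel when the overlap is odd), kept
regions are disjoint and tile the output exactly, and no blending is
performed.  Tile→forward→stitch with an identity model is bit-exact
(centering arithmetic is done in float64 so mean subtraction/restoration
round-trips float32 data exactly).  The streaming mode applies the same
half-overlap-discard rule at temporal junctions between consecutive batches;
the real system's three concurrent threads are emulated as sequential stages
because only the batch contract (boundaries, discard rule, ordering) is
observable.

## Synthetic data generator

The generator emulates 30-Hz two-photon calcium movies: anisotropic Gaussian
somata (default diameter 10 px, 20% radius jitter, minimum centroid
separation 8 px, rejection-sampled), homogeneous Poisson spike trains
(default 0.5 Hz), double-exponential transients (1−e^{−t/τ_r})·e^{−t/τ_d}
normalised to unit peak, a smooth positive neuropil background with a slow
multiplicative fluctuation, and optional vessel shadowing.  Default kinetics
are GCaMP6s-like — τ_r = 0.1 s, τ_d = 1.0 s — and each soma carries a
resting fluorescence (1.5 units versus a transient amplitude of 1.0 per
spike), so static anatomy dominates frame-to-frame variation and the clean
movie satisfies the slow-dynamics precondition (R > 0.99) that interleaved
self-supervision requires.  All intensities are in arbitrary units.

Noise: photon counts are Poisson(clean·photon_scale) and the output is
gain·counts/photon_scale (+ Gaussian read noise + offset), so the clean
intensity scale is preserved in expectation and only the noise level varies
with the relative photon number.  On a constant image the mean is μ and the
variance μ/photon_scale + σ² (tested to 3 standard errors over 10⁶ voxels).
When no template sigma is given, calibration sets σ to 10% of the Poisson
standard deviation at the mean intensity, keeping shot noise dominant.  The
imaging SNR (10·log₁₀ ‖y‖²/‖x−y‖², y the clean movie) is monotone in
photon_scale, so a requested level is found by bisection on
log(photon_scale) and realised within ±0.25 dB at the calibration seed.

What the generator does **not** model: optical PSF blur of the rendering,
dendrites and axons, motion, haemodynamics, bleaching.  Passing tests
therefore demonstrate the correctness of the training/inference machinery
and noise model, not performance on the full complexity of in vivo data.

## Event quantification

Release-event geometry is computed from annotated centers in 4D (x, y, z, t)
volumes: 1D profiles at the peak time (events closer than the profile
half-width to the volume edge are excluded), least-squares Gaussian fits
(A·e^{−(x−μ)²/2σ²}+b; non-convergent or flat profiles flag the event), then
Richardson–Lucy deconvolution of the fitted curve (baseline removed,
resampled at 0.1 px) against the Gaussian system PSF — default lateral FWHM
0.6 μm, axial 3.5 μm, converted to pixels via the pixel size / plane
spacing.  RL uses multiplicative updates with circular (FFT) boundary
handling, which conserves total mass to ~10⁻⁶ relative; the default 50
iterations is configurable, and 200 iterations bring the deconvolved width
of a σ=2 px Gaussian observed through a σ=1 px PSF within 2% of the analytic
√3·2.3548 px.  The diameter per axis is the FWHM (linear interpolation at
half of peak−baseline) of the deconvolved curve; plane ellipticities are
(a−b)/a with a the larger and b the smaller of the plane's two diameters,
so values lie in [0, 1).  Event detection itself is out of scope — centers
are inputs, as in the manual-annotation workflow the pipeline mirrors.

Temporal binning uses half-open bins [k·w, (k+1)·w); a boundary event goes
to the later bin.

## Numerical and I/O conventions

Arrays are (x, y, t): TIFF pages map to t ascending, rows to y, columns
to x.  Writing integer output quantises round-half-even and errors on
overflow unless clipping is requested; float32 round trips are bit-exact;
BigTIFF engages above 4 GB.  Correlations are computed in double precision;
constant slices are skipped and masked rather than zero-filled.  IoU of two
empty masks is defined as 1 (vacuous agreement).  Peak ΔF/F₀ masks pixels
with nonpositive baseline.  The paired before/after comparison helper is a
one-sided paired t-test without multiple-testing correction.

## Scaled problem sizes

The test suite and the acceptance script exercise the end-to-end pipeline at
reduced scale — 128×128×600 movies, the quarter-width model, 32³ patches,
300 optimisation steps — chosen so the whole cycle is a few minutes of CPU
work while leaving a wide margin over the ≥5 dB gain and correlation-
improvement checks (measured gain ≈ 19 dB).  Full-size training (150³
patches, 3,000 pairs, 20 epochs, full-width model) uses the same code paths
but is a GPU-scale workload; its published absolute output-SNR figures are
not reproduced here.

## Known limitations

- The numpy engine is single-device and far slower than a GPU framework;
  it is intended for correctness, moderate-scale use and testing.
- Batch size defaults to 1 (the multi-GPU batch rule of the original
  setting has no analogue here); gradients accumulate across a configured
  batch before each Adam step.
- The simplified generator cannot validate behaviour on anatomical detail
  it does not render (dendrites, vessels' temporal dynamics, motion).
- Richardson–Lucy with circular boundaries assumes the profile decays to
  near-baseline within the window; profiles truncated by the window edge
  bias the recovered width.
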