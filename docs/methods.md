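# Methods

## The model

`noisemapnet` denoises dynamic magnitude MR images by *residual noise-map
estimation*: a 2D U-Net `f_θ` maps a standardized magnitude image `x` to an
estimate of its additive noise component `n̂ = f_θ(x)`, and the denoised
image is the subtraction `x − n̂`. The network never regresses the clean
image directly; learning the residual is easier because the noise map is
close to zero-mean and structure-free, and it makes the method auditable —
the predicted noise map can be inspected for anatomical structure leakage.

The noise model is additive zero-mean Gaussian on the magnitude image.
This is an approximation: magnitude MR noise is Rician, which at the
moderate-to-high SNR of the blood pool is close to Gaussian but deviates in
dark background regions. Rician noise simulation is a known extension and
is deliberately not implemented.

### Architecture

Symmetric encoder–decoder with skip connections, fully convolutional:

* encoder depth `d` (default 4) with `f` initial 3×3 filters (default 64),
  the channel count doubling at each level (64, 128, 256, 512, and 1024 at
  the bottleneck for the defaults);
* two convolutions per resolution level, each followed by batch
  normalization and ReLU; 2×2 max pooling (stride 2) between levels;
* 2×2 transposed convolutions (stride 2) in the decoder, with the matching
  encoder level's pre-pool features concatenated before the decoder block;
* dropout (default rate 0.5) at the bottleneck only;
* a final linear 1×1 convolution, so predicted noise values can be
  negative.

Inputs must have sides divisible by `2^d`; arbitrary frames are
zero-padded to the next multiple and cropped back after prediction.

Open points in the architecture description were resolved as follows and
are flagged here as assumptions: two convolutions per level (the standard
U-Net block), dropout at the bottleneck only, concatenation as the skip
merge, and 2×2/stride-2 transposed convolutions. The normalization /
activation ordering is configurable; the default is conv → BN → ReLU, the
ordering used by the reference U-Net implementations this design follows,
which also proved markedly more stable here under batch-size-1 statistics
(`bn_after_activation=True` gives conv → ReLU → BN).

The layers, backward passes and the Adam optimizer are implemented
directly on NumPy (`_autograd.py`): convolution via im2col + BLAS, exact
2×2 pooling/up-sampling, spatial batch statistics per single sample.
Gradients are verified against central finite differences in float64.

## Training regime

* **Loss**: mean squared error (L2) between predicted and ground-truth
  noise maps.
* **Optimizer**: Adam, β₁ = 0.9, β₂ = 0.99; the library default learning
  rate is 1e-5 (appropriate for a full-size corpus); ε is the conventional
  1e-8.
* **Batching**: batch size 1, 64×64 patches drawn uniformly at random from
  each training frame; an *epoch* is one pass over
  `frames × patches_per_frame` patches (the patch count per frame is not a
  canonical value; it is a throughput knob).
* **Noise regeneration**: the Gaussian noise added to a patch is drawn
  fresh for every patch at every epoch from a counter-based substream of
  the master seed (`(master_seed, epoch, index)`), so no noise realization
  is ever reused, yet every sample is exactly reproducible.
* **Split**: subjects (not frames) are partitioned 80/20 into train and
  validation, so no subject's anatomy appears on both sides.
* **Early stopping**: at most 500 epochs; stop when the validation loss
  has not improved for 20 consecutive epochs; improvement means strictly
  lower than the best by ≥ 1e-7 (guards against float noise re-arming the
  patience); the best-epoch weights are restored. The validation noise is
  drawn once, before the first epoch, and frozen — resampling it each
  epoch would add stochastic jitter to the stopping signal.

### Standardization

Noise is injected in the raw intensity domain, where the SNR calibration
lives. Both the noisy and the clean patch are then scaled with the *same*
standardization parameters, making the ground-truth noise map exactly
their standardized difference, and the inverse mapping of a predicted map
a pure multiplication by sigma (the mean offset cancels in the
difference).

The parameters used for a training patch are those of its **source
frame**, computed analytically from the clean frame and the known noise
level: `mu = mean(clean)`, `sigma = sqrt(var(clean) + sigma_noise²)`.
This matters: z-scoring each 64×64 patch by its own statistics would
present the network with noise at a standardized amplitude systematically
different from what full-frame standardization produces at inference
(a flat patch normalizes its own noise to unit variance), and measurably
caps the fraction of noise the trained model removes. With frame-level
parameters, train-time and inference-time scaling are identical.

At inference the default is per-frame standardization (each dynamic is
scaled independently), so bolus-driven intensity swings do not leak
between frames; per-series parameters are available as an option.

## Synthetic phantoms

The generators provide image-domain stand-ins for data that cannot be
shipped: no k-space, coil sensitivity, aliasing or motion simulation.

* **Cine phantom** (training): a short-axis heart as concentric discs —
  bright LV blood pool, darker myocardial ring, dim background — with
  exactly piecewise-constant intensities (so ROI statistics are exact) and
  a smooth cosine contraction/relaxation of the radii across frames. These
  act as the high-SNR, approximately noise-free training references.
* **Perfusion phantom** (evaluation): static geometry whose blood-pool and
  myocardial intensities follow gamma-variate bolus kinetics
  `g(t) = ((t−t0)/τ)^a · exp(−(t−t0)/τ)` normalized to unit peak (peak at
  `t0 + a·τ`), blood enhancing earlier and more strongly than myocardium.
  Defaults: 40 dynamics, blood `t0=8, a=3, τ=4` (baseline 60, peak 400),
  myocardium `t0=12, a=3, τ=6` (baseline 80, peak 200), background 40,
  in intensity a.u.; pixel spacing 1×1 mm.
* **Noise**: zero-mean Gaussian. SNR is defined as the ROI mean signal at
  the frame of maximum ROI mean divided by the noise standard deviation —
  the simplest convention consistent with calibrating "SNR ≈ 10 in the LV
  blood pool"; with it, sigma = ROI mean / target SNR. An optional
  radial-gradient sigma map emulates g-factor-like spatially varying noise
  (sigma rising linearly with distance from the center pixel). Negative
  noisy pixels are kept so `noisy = clean + noise` holds exactly; clipping
  negatives is an inference-time display option (default on for magnitude
  outputs, with the unclipped noise map always preserved so the
  conservation identity stays auditable). Each (slice, dynamic) frame
  draws from its own counter-based substream, so realizations are
  independent of frame order.

What the phantoms do **not** emulate: anatomical texture and partial
voluming (tissues are piecewise constant, so edges are idealized steps),
cardiac/respiratory motion in the perfusion series, Rician noise, and
reconstruction artifacts. Passing the synthetic benchmarks therefore
demonstrates the machinery is correct and the method behaves as designed
on idealized data; it does not by itself establish in-vivo performance.

## Evaluation metrics

* **Sharpness index**: profiles are cast across the blood–myocardium
  interface between two non-intersecting curves flanking the border, at
  matched arc-length fractions (1 mm apart along the curve by default),
  sampled by bilinear interpolation with a step of half the finer pixel
  spacing. Per profile, `d` is the distance between the first upward
  crossing of `min + 0.2·range` and the first subsequent crossing of
  `min + 0.8·range` (linear sub-sample interpolation, ties toward the
  earlier sample); the index is `1/d` in mm⁻¹, averaged over all accepted
  profiles. Flat profiles and profiles that never complete the rise are
  rejected and counted. Range normalization makes the index invariant to
  affine intensity changes.
* **Temporal-profile NMSE**: `Σ(ref − s·test)² / Σ(ref²)` over the
  first-pass window, with `s = Σ(ref·test)/Σ(test²)` (the closed-form
  least-squares minimizer) when scale matching is requested and `s = 1`
  otherwise, so scaling bias stays visible. The energy normalizer is a
  documented convention; `Σ(ref − mean)²` is available as a flag. The
  default first-pass window starts at the first dynamic exceeding the
  signal minimum by 10% of the range and ends one upslope-width past the
  peak; an explicit window always overrides the rule.
* **PSNR**: `10·log10(peak²/MSE)` against the known clean phantom (peak
  from the clean image) — the objective stand-in, on synthetic data, for
  subjective image-quality reading.

## The desk-scale demonstration

The default demo (`noisemapnet.pipeline.run_demo`, also what
`scripts/acceptance.py` executes) reproduces the study design at a size a
single CPU handles in a few minutes:

* 10 synthetic subjects × 4 cine frames (128×128), each subject with its
  own ventricle size, center offset and tissue intensities; blood-pool
  SNR 10; subject-level 80/20 split (32 train / 8 validation frames);
* toy network: depth 2, 8 initial filters, dropout 0.5;
* training: Adam lr 1e-3, 4 patches per frame, at most 30 epochs with
  patience 20 (the higher learning rate and small epoch cap are the
  scaled-down counterparts of the full-size regime);
* evaluation: a held-out 40-dynamic perfusion phantom at SNR 10, scored
  with series PSNR, noise-map sigma ratio (per-64×64-patch standard
  deviation of the predicted maps vs the simulated sigma), the absolute
  Pearson correlation between predicted noise maps and the clean
  edge-gradient image (structure leakage), myocardial sharpness at peak
  enhancement, and first-pass blood-pool NMSE.

### Known limitation: sharpness at toy scale

The toy network's residual error concentrates in a narrow band at the
blood–myocardium step edge. Because the phantom edge is an idealized
sub-pixel step (clean index ≈ 1.39 mm⁻¹, versus ~0.65 mm⁻¹ for real
myocardial borders), a small localized misfit inflates the measured
20–80% rise noticeably, and the denoised-vs-clean sharpness deficit
fluctuates around and mostly above 10% (0.06–0.21 across training seeds). The
other demo metrics (PSNR gain ≈ 11 dB, sigma ratio ≈ 0.85–0.9, structure
correlation ≈ 0.01, blood NMSE < 1e-3) are stable across seeds. Deeper
networks, more filters, or longer training resolve the edge misfit but
fall outside the deliberately capped demo budget.

## Numerical choices

* Network computations in float32; metrics and phantoms in float64.
* He-normal weight initialization; BN eps 1e-5, momentum 0.1.
* Max-pool ties resolve to the first (raster-order) element.
* Constant frames are rejected wherever a standard deviation would be
  zero (standardization, sharpness of flat profiles, PSNR of a constant
  reference), with explicit errors; degenerate constant training patches
  are skipped with a warning rather than aborting an epoch.
* Padding places the extra pixel on the bottom/right for odd remainders;
  crop inverts it exactly.
* Denoising is not idempotent (a second application sees a different
  input distribution); nothing relies on it.
* All randomness flows from one master seed through named
  `SeedSequence` substreams (model init, patch positions, per-epoch noise,
  dropout, validation noise, evaluation noise), so any single sample, and
  the whole pipeline, is reproducible bit-for-bit on the same platform.
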