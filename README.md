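# noisemapnet

Residual noise-map denoising for dynamic cardiac MR perfusion imaging.

First-pass myocardial perfusion CMR trades SNR for speed: accelerated
acquisitions reconstructed with parallel imaging leave substantial noise
in the dynamic image series, which degrades visual reading and
quantitative analysis. This package implements a learning-based
post-reconstruction denoiser for such series: a 2D U-Net takes a
magnitude image `x` and predicts its **noise map** `n̂`; the denoised
image is the subtraction

```
x_denoised = x − n̂,   n̂ = f_θ(x)
```

Because the model estimates the noise rather than the clean image, the
predicted maps can be audited directly — a good model produces
Gaussian-looking, anatomy-free noise maps, and the conservation identity
`input = denoised + noise map` holds exactly.

The package is aimed at researchers who want to study this residual
denoising scheme end to end without access to patient data. It bundles:

* the U-Net (encoder depth 4, 64 initial 3×3 filters by default, skip
  connections, bottleneck dropout), with layers, backpropagation and the
  Adam optimizer implemented directly on NumPy;
* the training regime: L2 loss on noise maps, Adam (β₁=0.9, β₂=0.99),
  batch size 1, random 64×64 patches, noise regenerated per patch per
  epoch, subject-level 80/20 split, patience-20 early stopping;
* synthetic cardiac phantoms: high-SNR cine-like frames for training and
  gamma-variate first-pass perfusion series for evaluation, corrupted
  with Gaussian noise calibrated to a target blood-pool SNR (optionally
  spatially varying);
* the evaluation metrics used for perfusion reconstructions: myocardial
  sharpness index (1/d over the 20–80% intensity rise across the
  blood–myocardium interface), first-pass temporal-profile NMSE with
  optional least-squares scale matching, and PSNR against a known clean
  reference;
* NIfTI I/O and a CLI (`noisemapnet phantom/train/denoise/evaluate/run`).

See `docs/methods.md` for the model, conventions and limitations.

## Worked example

Train the desk-scale demo (10 synthetic subjects × 4 cine frames at
blood-pool SNR 10; toy U-Net with depth 2 and 8 filters; ≤30 epochs) and
evaluate it on a held-out 40-dynamic perfusion phantom:

```python
from noisemapnet.pipeline import run_demo

metrics, history, model = run_demo(seed=1)
for key in ("psnr_noisy_db", "psnr_denoised_db", "psnr_gain_db",
            "noise_sigma_ratio", "structure_correlation",
            "sharpness_clean_mm1", "sharpness_denoised_mm1",
            "blood_nmse_denoised"):
    print(f"{key:24s} {metrics[key]:.4f}")
```

prints (seed 1):

```
psnr_noisy_db            20.0052
psnr_denoised_db         30.7815
psnr_gain_db             10.7764
noise_sigma_ratio        0.8244
structure_correlation    0.0160
sharpness_clean_mm1      1.3914
sharpness_denoised_mm1   1.3120
blood_nmse_denoised      0.0004
```

Reading these numbers: denoising raises the series PSNR by ~11 dB over
the noisy input; the predicted noise maps carry ~82% of the true
simulated noise amplitude (`noise_sigma_ratio`, per-patch σ of the
predicted maps / true σ); they are essentially uncorrelated with the
anatomy (`structure_correlation` ≈ 0.02, i.e. no structure leaked into
the noise maps); the myocardial edge sharpness of the denoised image
stays close to the clean phantom's; and the first-pass blood-pool signal
curve is reproduced without bias (NMSE ≈ 4e-4). Sharpness preservation is
the one metric that varies noticeably with the training seed at this toy
scale — see the limitations section of `docs/methods.md`.

The same pipeline is available from the shell, writing NIfTI volumes, a
checkpoint, a JSON-lines training log, a metrics report and a manifest:

```bash
noisemapnet run --seed 1 --out-dir runs/demo
noisemapnet phantom --kind perfusion --size 128 --dynamics 40 --snr 10 \
    --seed 3 --out phantoms/
```

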