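# selfdenoise3d

Self-supervised denoising of fluorescence time-lapse imaging, for
experimenters working at the photon-shot-noise limit — calcium imaging,
immune-cell migration, neurotransmitter sensors — where clean reference
recordings do not exist.

## The method

Photon detection is Poisson: two consecutive frames of a time-lapse stack
carry nearly identical underlying signal but statistically independent shot
noise.  Splitting a block of 2·s adjacent frames into its even-index and
odd-index substreams therefore yields a valid Noise2Noise training pair
(input, target) without any ground truth.  A network f minimising

    L = ½·( mean|f(x) − y|  +  mean(f(x) − y)² )

over such pairs converges toward the expected signal.  The network is a
lightweight all-3D U-Net (3×3×3 convolutions, 2×2×2 max pooling, trilinear
upsampling, skip concatenations) with exactly **1,020,337** trainable
parameters — a 94% reduction from the 16,315,585-parameter reference it was
pruned from — trained with Adam (learning rate 5×10⁻⁵, moment decays 0.5 and
0.9) under 12-fold augmentation (random input/target swap × six x-y
flips/rotations).  Model compression plus augmentation suppresses
overfitting, so the last-epoch model is the final solution.

Whole stacks are denoised by overlapped 3D tiling (default 150³ patches, 40%
overlap; a 490×490×300 stack becomes 75 patches, ~2.53×10⁸ voxels through
the network) with margin-discard stitching: half of every overlap is
discarded so each output voxel is written exactly once.  The same
half-overlap-discard rule drives a streaming mode that emulates real-time
acquisition→processing→display batching.

The package also ships:

- a synthetic calcium-movie generator (Gaussian somata with Poisson spike
  trains and double-exponential transients, fluctuating neuropil, optional
  vessels) degraded by calibrated mixed Poisson–Gaussian noise, so every
  stage is testable offline;
- the evaluation suite: SNR = 10·log₁₀(‖y‖²/‖x−y‖²), Pearson R, slice-wise
  correlations along x/y/t, IoU and majority-vote consensus masks, peak
  ΔF/F₀ maps;
- release-event quantification: Gaussian profile fits, Richardson–Lucy
  deconvolution against the system PSF (lateral 0.6 μm / axial 3.5 μm
  Gaussian model), per-axis FWHM diameters, per-plane ellipticities
  (a−b)/a, and temporal binning.

The neural-network engine (3D convolutions with hand-derived backprop, Adam)
is implemented directly on numpy; no deep-learning framework is required.

## Worked example

```python
import numpy as np
from selfdenoise3d import (make_denoising_fixture, UNet3DConfig, TrainConfig,
                           fit, denoise_stack, snr_db)

# paired clean/noisy synthetic movie, calibrated to -2.5 dB input SNR
clean, noisy, model, manifest = make_denoising_fixture(-2.5, (128, 128, 600), seed=7)

# CPU-scale run: quarter-width model, 32^3 patches, 300 Adam steps
state = fit(noisy,
            UNet3DConfig(width_multiplier=0.25),
            TrainConfig(learning_rate=1e-3, epochs=2, n_pairs=150,
                        patch=(32, 32, 32), seed=1))
den = denoise_stack(state.final_model, noisy,
                    stack_mean=state.stack_mean, patch=(128, 128, 600))

print(f"input  SNR {snr_db(noisy.data, clean.data):6.2f} dB")
print(f"output SNR {snr_db(den.data,  clean.data):6.2f} dB")
```

prints (about two minutes on one CPU):

```
input  SNR  -2.46 dB
output SNR  16.53 dB
```

i.e. training on nothing but the noisy movie itself recovers ~19 dB of SNR;
the mean frame-wise Pearson correlation against the clean movie rises from
0.21 to 0.95.  Paper-scale runs use the full-width model, 150³ patches,
3,000 pairs and 20 epochs (`TrainConfig()` defaults).

The same pipeline is scriptable from the shell:

```sh
selfdenoise3d simulate --seed 42 --snr-db -2.5 --out clean.tif noisy.tif
selfdenoise3d train    --input noisy.tif --config train.yaml --out model.npz
selfdenoise3d denoise  --input noisy.tif --model model.npz --out denoised.tif
selfdenoise3d evaluate --test denoised.tif --ref clean.tif --out report.json
```

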