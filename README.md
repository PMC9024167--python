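# drdseg

Denoising, segmentation and reward-driven refinement for 2D/3D
multimodal medical images (CT, radiographs, ultrasound-like
speckle-corrupted data), built for researchers who need a fully
inspectable, CPU-only reference implementation of a three-stage
pipeline:

1. **Denoise** — Bayesian wavelet shrinkage with a level-adaptive
   threshold plus an edge-preserving bilateral filter on the coarsest
   band. Detail coefficients are shrunk by the Laplace-prior MAP rule
   gated at `T_j = 2^(J−j+1) σ_N √(2 ln M)`:

       ĝ = 0                                if |f| ≤ T_j
       ĝ = sgn(f) · max(|f| − σ_N²/s, 0)    if |f| > T_j

   applied to the LH/HL/HH subbands of a J-level DWT of the
   log-transformed image, with the bilateral filter
   `h(x) = k(x)⁻¹ Σ_ξ f(ξ) c(ξ,x) s(f(ξ),f(x))` smoothing `LL^J`.

2. **Segment** — a residual U-Net with a 4-branch dilated-convolution
   context module (rates 3, 5, 7, 9) at the bottleneck and group
   normalization throughout, emitting per-voxel foreground
   probabilities. Runs on a small built-in numpy autodiff engine.

3. **Refine** — a reinforcement-style loop over the binarization
   threshold driven by the interest-weighted Jaccard
   `W = (B/H)·|u∩v|/|u∪v|`, per-step reward `f_t = sign(ΔW)`,
   discounted return `Q = Σ κ^{t−1} f_t` and a χ-greedy policy
   (χ: 0.9 → 0.1).

Evaluation metrics (SSIM, SNR in dB, relative overlap = Jaccard, region
accuracy `|T∩S|/|S|`) and a synthetic phantom generator with exact
ground-truth masks make every stage testable without external data.
See `docs/methods.md` for the model details and design choices.

## Worked example

```python
import numpy as np
from drdseg import generate_phantom, corrupt, NoiseSpec
from drdseg.denoise import denoise_image
from drdseg.metrics import snr_db, ssim

phantom = generate_phantom((84, 84), n_lesions=2, contrast=0.4, seed=7)
noisy = np.clip(corrupt(phantom.image, NoiseSpec(sigma=0.2, seed=8)), 0, None)
denoised = denoise_image(noisy)

print(f"SNR noisy    {snr_db(phantom.image, noisy):.2f} dB")
print(f"SNR denoised {snr_db(phantom.image, denoised):.2f} dB")
print(f"SSIM         {ssim(phantom.image, denoised):.3f}")
```

prints

```
SNR noisy    14.14 dB
SNR denoised 23.23 dB
SSIM         0.864
```

— the speckled phantom (multiplicative Gamma noise, σ = 0.2) starts at
14 dB against the known clean image; wavelet shrinkage plus bilateral
filtering recovers ~9 dB while keeping structural similarity high.

The same thing from the shell, end to end (simulate → denoise → train →
segment → refine → evaluate):

```bash
drdseg run --seed 7 --out-dir out/
```

which writes every stage's artifact (`noisy.nii`, `denoised.nii`,
`prob.nii`, `mask_refined.nii`, …), a `report.json` with the four
metrics, and a `manifest.json` with SHA-256 hashes of all artifacts —
reruns with the same seed are byte-identical. Individual stages are
available as `drdseg simulate|denoise|train|segment|refine|evaluate`,
each a thin wrapper over the corresponding library function.

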