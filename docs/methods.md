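# Methods

This note records the models implemented in `drdseg`, the assumptions
they rest on, the defaults chosen where the design was genuinely open,
and what the synthetic phantoms do and do not establish about behavior
on real data.

## Noise model and denoiser

The denoiser targets speckle: multiplicative, granular noise typical of
ultrasound and present in other modalities. The observed image is
modeled as `f = g · u` with `u` a positive unit-mean multiplier, so that
after a log transform the corruption is approximately additive, and in
the wavelet domain approximately Gaussian with standard deviation
`σ_N`. Noise-free detail coefficients are modeled as Laplace-distributed
with scale `s` (the generalized-Laplace shape parameter fixed at
`v = 1`). The MAP estimate of a coefficient under this pair of priors is
the soft rule `ĝ = sgn(f) · max(|f| − σ_N²/s, 0)`, and the implemented
shrinkage gates it with a level-dependent hard threshold:

    T_j = a_j · σ_N · √(2 ln M),   a_j = 2^(J−j+1),   j = 1 … J,

i.e. the universal threshold scaled by a dyadic per-level factor — the
finest level (j = 1) is thresholded hardest, and `T_j / T_{j+1} = 2`
exactly. `M` is the coefficient count of the subband being shrunk, not
of the whole image. The gate and the soft subtraction are independent
parameters of the rule; when `σ_N²/s < T_j` the rule is discontinuous at
the gate. This is deliberate and implemented exactly as stated. Note the
soft subtraction means the rule is *not* idempotent (reapplying shrinks
again); only the pure hard gate is.

Processing chain per 2D slice: `log → J-level separable DWT (detail
subbands LH/HL/HH per level, LL recursed) → shrink all detail subbands →
bilateral-filter LL^J → inverse DWT → exp`. Volumes are processed
slice-wise: the four-subband scheme is inherently 2D, and a separable 3D
transform is left as an extension.

Choices the formulation leaves open, fixed as follows:

- **Wavelet**: `db4` (compactly supported, orthogonal, perfect
  reconstruction); configurable.
- **Decomposition depth**: `J = 3` by default.
- **σ_N estimation**: median absolute deviation of the finest diagonal
  subband, `median(|HH¹|)/0.6745` — the standard robust estimator.
- **Laplace scale**: moment matching, `s = √(max(var − σ_N², 10⁻¹²)/2)`;
  the floor keeps `s > 0` on pure-noise subbands, where the soft
  subtraction then removes (essentially) everything above the gate.
- **Log base**: natural log, matching the `√(2 ln M)` universal-threshold
  form. Offset `ε = 10⁻³` admits zero-valued voxels; `exp(·) − ε`
  inverts it and the output is clamped non-negative.
- **Bilateral kernels**: Gaussians, `c = exp(−‖ξ−x‖²/2σ_d²)` and
  `s = exp(−(f(ξ)−f(x))²/2σ_r²)`, normalized to unit DC gain; window
  half-width `2⌈σ_d⌉`; symmetric padding everywhere (as for the DWT).
  Defaults `σ_d = 2` voxels, `σ_r = 0.1` intensity units (the LL band
  lives on the log-intensity scale). As `σ_r → ∞` the filter reduces to
  windowed Gaussian smoothing; for `σ_r` far below an edge height it
  leaves the edge's half-height crossing in place.

## Segmentation network

A U-shaped encoder-decoder built from residual units
(`m = h(b) + I(b, w)`, `I` = conv → GroupNorm → ReLU → conv, `h` the
identity or a 1×1 projection when channel counts change), 2× max-pool
downsampling, and a 4-branch dilated-convolution context module (ASPP)
at the bottleneck: each branch maps `4c → c` channels with a 3-tap
kernel at rates (3, 5, 7, 9) — receptive field `2r + 1` per axis — and
the branch outputs are concatenated back to `4c`. GroupNorm (8 groups)
keeps normalization batch-size independent. The head is a 1×1
convolution with a sigmoid, yielding per-voxel foreground probabilities.
`use_3d` switches every convolution to 3×3×3.

Unstated architecture details were fixed at minimal standard values:
depth 3, base width 16 (depth 2 / width 8 for the smallest test
problems), nearest-upsample + conv decoding, loss = soft Dice + binary
cross-entropy, full-batch Adam. "Deep supervision" is realized as
optional auxiliary sigmoid heads on intermediate decoder levels scored
against max-pool-downscaled masks at weight 0.5 each; it is off by
default and clearly an interpretation — the name implies it but no
scheme is specified. Each context branch sees the full `4c`-channel
input (a split is the other reading; full input is chosen).

The network runs on an in-repo reverse-mode autodiff engine over numpy
(float64). This keeps the package dependency-free beyond the scientific
stack and makes the algebraic contracts exactly testable: a
zero-initialized residual branch is a bit-exact identity, a stack of
identity-shortcut units telescopes to `b_N = b_n + Σ F(b_i, W_i)`, and
receptive fields are measured by gradient footprints. The cost is
speed: training is intended for desk-scale problems (≲ 100×100 images,
hundreds of optimizer steps), which the test suite and the acceptance
script use throughout. Demonstrating convergence, not clinical accuracy,
is the point of the training tests.

## Reward-driven refinement

Refinement treats the network's probability map as fixed and searches
over the binarization threshold. The overlap score of a candidate mask
`u` against the reference `v` is

    W = (B/H) · |u ∩ v| / |u ∪ v|,

the Jaccard index weighted by the interest fraction `B/H`; `B` is the
reference-foreground voxel count and `H` the total voxel count — the
only reading under which the weight is a fraction and `W ≤ 1`. The
per-step reward is `f_t = sign(W_{t+1} − W_t) ∈ {−1, 0, +1}`, episode
quality is `Q = Σ_t κ^{t−1} f_t`, and exploration is χ-greedy with χ
annealed 0.9, 0.8, … 0.1 per episode.

The loop's state, action set and learner are design choices: state =
(probability map, current threshold), actions = {raise threshold by δ,
lower by δ, accept} with δ = 0.05, and a tabular action-value table over
the discretized thresholds. Penalized moves (`f_t = −1`) are reverted
before the next step, so greedy (χ = 0) episodes have non-decreasing
overlap at accepted moves. Because thresholding is a known,
deterministic environment, the table is initialized by value iteration
over the threshold chain — `V(θ)` is the best overlap reachable from θ
through non-penalized moves — and is backed up from the observed rewards
during the episode. Greedy ties prefer `accept` (termination at an
optimum) and otherwise the least-tried action, which systematically
covers score plateaus. Under these rules a χ = 0 episode with enough
steps provably attains the best overlap reachable through non-penalized
moves; a pure per-step hill-climb does not, because `W(θ)` is generally
multimodal. `t_max` should be a small multiple of the grid size (64 is
the default for a 19-node grid; the enumeration tests use 512 to cover
plateau exploration worst cases).

Refinement runs as a post-network stage; because the reward needs a
reference mask, it is a supervised-evaluation tool (and could equally
shape training), not an unsupervised inference step.

## Metrics

- **SSIM**: exponent-weighted product `l^α c^β s^γ` of the standard
  luminance/contrast/structure comparisons over a sliding Gaussian
  window (default 7×7, SD 1.5; α = β = γ = 1; stabilizers
  `C1 = (0.01 L)²`, `C2 = (0.03 L)²`, `C3 = C2/2` with `L` the reference
  dynamic range). At unit exponents this reduces algebraically to the
  usual combined formula and is cross-checked against scikit-image.
- **SNR**: `10 log₁₀(Σ signal² / Σ residual²)` dB; `+∞` on zero
  residual. With no clean reference the pipeline reports the residual
  SNR against the noisy input and flags the convention in its manifest.
- **Relative overlap**: Jaccard `|T∩S|/|T∪S|`; 0 on an empty union.
- **Region accuracy**: `|T∩S|/|S|` exactly as written — this is the
  precision of the segmented region, so it is exposed as
  `accuracy_eq20` with conventional per-voxel accuracy available
  separately (`pixel_accuracy`).

## Synthetic phantoms

Phantoms emulate the salient structure of chest-CT / radiograph / CT
lesion data: a smooth low-frequency background (three random cosine
modes inside a soft circular body boundary) plus circular/spherical
lesions of known center and radius, with configurable additive contrast
(default 0.4). The mask is the exact hard-edged union of the lesion
balls; the rendered image feathers lesion rims with a super-Gaussian
profile so edge-preservation can be probed while ground truth stays
analytic. Speckle uses a Gamma(1/σ², σ²) multiplier — positive, unit
mean, SD σ, the classic ultrasound surrogate — with σ = 0.2 as the
default study condition (the source datasets' noise levels are not
stated anywhere, so this is a free parameter fixed once at a level where
the noisy image is visibly degraded, ~14 dB SNR at 84×84). Additive
Gaussian noise is available for directly acquired images.

What passing tests on phantoms do **not** show: performance on real
anatomy (textured backgrounds, non-ellipsoidal lesions, partial-volume
effects, scanner-specific noise), behavior at clinical resolutions, or
the generalization of a trained network beyond its training images — the
training checks are deliberate overfitting exercises that verify
gradient flow and capacity, nothing more.

## Numerical conventions

- All randomness flows through `numpy.random.default_rng` seeds;
  identical seeds give bit-identical phantoms, episodes and training
  runs, and the pipeline manifest records SHA-256 hashes of every
  artifact to make this checkable.
- Coefficients exactly at threshold are zeroed (the gate is non-strict).
- The training BCE term is computed from pre-sigmoid logits (gradient
  `σ(z) − y`), which keeps gradients alive if the head saturates early;
  BCE on probabilities can stall there.
- Empty-union Jaccard is 0; accuracy with an empty segmented region is
  an error (the pipeline reports 0 for an empty refined mask rather than
  failing).
- Wavelet and bilateral stages both use symmetric boundary extension;
  reconstructions are cropped to the original shape for odd sizes.
- Pipeline artifacts are written as uncompressed NIfTI so that repeated
  runs are byte-identical (compressed containers embed timestamps).
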