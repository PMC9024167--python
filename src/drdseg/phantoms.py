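"""Synthetic anatomical phantoms with exact ground-truth masks.

Real multimodal studies (chest CT, chest radiographs, CT lesion archives)
provide a smooth anatomical intensity field with one or more compact
lesions.  The phantoms here emulate that structure: a low-frequency
background modulated by a soft body boundary, plus ellipsoidal (circular
in 2D) lesions whose voxel membership is known analytically, corrupted by
either additive Gaussian noise or multiplicative speckle.  Speckle is the
multiplicative granular noise of ultrasound; after a log transform it is
approximately additive and Gaussian, which is the assumption the wavelet
denoiser is built on.

Everything is driven by ``numpy.random.default_rng`` seeds: identical
seed and parameters give bit-identical arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LesionSpec", "Phantom", "NoiseSpec", "generate_phantom", "corrupt"]


@dataclass(frozen=True)
class LesionSpec:
    """One spherical (circular in 2D) lesion.

    center : voxel coordinates of the lesion center (floats).
    radius : lesion radius in voxels.
    contrast : additive intensity contrast; negative gives a dark lesion.
    """

    center: tuple[float, ...]
    radius: float
    contrast: float


@dataclass(frozen=True)
class Phantom:
    """A synthetic image with its exact segmentation ground truth.

    ``mask`` is precisely the union of the hard-edged lesion balls in
    ``lesion_specs``; the rendered ``image`` feathers lesion edges with a
    super-Gaussian profile so edge-preservation claims can be tested
    while the ground truth stays analytic.
    """

    image: np.ndarray
    mask: np.ndarray
    lesion_specs: tuple[LesionSpec, ...]
    seed: int

    def __post_init__(self) -> None:
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask must have identical shape")


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model for :func:`corrupt`.

    model : ``"additive_gaussian"`` or ``"multiplicative_speckle"``.
    sigma : noise SD.  Intensity units for additive noise; unitless SD of
        the unit-mean multiplier for speckle.  ``sigma = 0`` is a no-op.
    seed : RNG seed.
    """

    model: str = "multiplicative_speckle"
    sigma: float = 0.2
    seed: int = 0

    _MODELS = ("additive_gaussian", "multiplicative_speckle")

    def __post_init__(self) -> None:
        if self.model not in self._MODELS:
            raise ValueError(f"unknown noise model {self.model!r}; use one of {self._MODELS}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def _background(shape: tuple[int, ...], rng: np.random.Generator) -> np.ndarray:
    """Smooth anatomical background: a few cosine modes inside a soft body disc."""
    axes = [np.linspace(-1.0, 1.0, n) for n in shape]
    grids = np.meshgrid(*axes, indexing="ij")
    r = np.sqrt(sum(g * g for g in grids))
    body = 1.0 / (1.0 + np.exp((r - 0.92) / 0.04))  # soft circular boundary

    field_ = np.full(shape, 0.45)
    for _ in range(3):
        freqs = rng.integers(1, 4, size=len(shape))
        phases = rng.uniform(0.0, 2.0 * np.pi, size=len(shape))
        amp = rng.uniform(0.03, 0.08)
        mode = np.ones(shape)
        for g, f, p in zip(grids, freqs, phases):
            mode = mode * np.cos(np.pi * f * g + p)
        field_ = field_ + amp * mode
    return np.clip(field_ * body + 0.05, 0.0, 1.0)


def generate_phantom(
    shape: tuple[int, ...],
    n_lesions: int = 2,
    contrast: float = 0.4,
    seed: int = 0,
) -> Phantom:
    """Generate a phantom image with ``n_lesions`` lesions and its exact mask.

    Parameters
    ----------
    shape
        Grid dimensions (2D or 3D); every dimension must be >= 16.
    n_lesions
        Number of lesions (>= 0).
    contrast
        Additive lesion contrast applied to the image.
    seed
        RNG seed; identical seed and parameters give bit-identical output.
    """
    shape = tuple(int(n) for n in shape)
    if any(n < 16 for n in shape):
        raise ValueError(f"every dimension must be >= 16, got {shape}")
    if n_lesions < 0:
        raise ValueError("n_lesions must be >= 0")

    rng = np.random.default_rng(seed)
    image = _background(shape, rng)
    mask = np.zeros(shape, dtype=np.uint8)

    idx = np.indices(shape).astype(float)
    min_side = min(shape)
    specs: list[LesionSpec] = []
    for _ in range(n_lesions):
        center = tuple(rng.uniform(0.25 * n, 0.75 * n) for n in shape)
        radius = float(rng.uniform(min_side / 16.0, min_side / 8.0))
        specs.append(LesionSpec(center=center, radius=radius, contrast=float(contrast)))

    for spec in specs:
        d2 = np.zeros(shape)
        for ax, c in enumerate(spec.center):
            d2 += (idx[ax] - c) ** 2
        d = np.sqrt(d2) / spec.radius
        mask[d <= 1.0] = 1
        # feathered rendering: ~flat core, rapid super-Gaussian falloff at the rim
        image = image + spec.contrast * np.exp(-(d**4))

    return Phantom(
        image=np.clip(image, 0.0, 1.0),
        mask=mask,
        lesion_specs=tuple(specs),
        seed=int(seed),
    )


def corrupt(image: np.ndarray, noise: NoiseSpec) -> np.ndarray:
    """Apply the noise model of ``noise`` to ``image``.

    Additive Gaussian adds iid N(0, sigma^2).  Multiplicative speckle
    multiplies by iid Gamma(1/sigma^2, sigma^2) draws — positive, unit
    mean, SD ``sigma`` — so that a log transform renders the noise
    approximately additive.
    """
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite")
    if noise.sigma == 0:
        return image.copy()
    rng = np.random.default_rng(noise.seed)
    if noise.model == "additive_gaussian":
        return image + rng.normal(0.0, noise.sigma, size=image.shape)
    k = 1.0 / noise.sigma**2
    multiplier = rng.gamma(shape=k, scale=noise.sigma**2, size=image.shape)
    return image * multiplier
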