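"""Hybrid wavelet-shrinkage / bilateral-filter denoiser.

The chain models speckle (multiplicative) noise: a log transform makes it
approximately additive Gaussian, a J-level separable 2D wavelet
decomposition splits the signal into LL/LH/HL/HH subbands, the detail
subbands are shrunk with a level-adaptive Bayesian rule, the coarsest LL
band is smoothed with an edge-preserving bilateral filter, and the
inverse transform plus exponentiation returns the denoised image.

The shrinkage rule is the MAP estimate of a Laplace-distributed
noise-free coefficient observed under Gaussian noise of SD sigma_n,
gated by a level-dependent hard threshold

    T_j = a_j * sigma_n * sqrt(2 ln M),   a_j = 2^(J - j + 1),

where M is the number of coefficients in the subband and j runs from 1
(finest) to J (coarsest) — the universal threshold scaled by a dyadic
per-level factor.  Above the gate, coefficients are soft-shrunk by
sigma_n^2 / s where s is the Laplace scale of the subband.

Noise SD is estimated by the median absolute deviation of the finest
diagonal subband (MAD / 0.6745); the Laplace scale by moment matching,
var(f) = sigma_g^2 + sigma_n^2 and s = sigma_g / sqrt(2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pywt

__all__ = [
    "SubbandPyramid",
    "SubbandStats",
    "ThresholdSchedule",
    "BilateralParams",
    "log_transform",
    "inverse_log_transform",
    "decompose",
    "reconstruct",
    "estimate_sigma_n",
    "threshold_schedule",
    "estimate_laplace_scale",
    "shrink",
    "bilateral",
    "denoise_image",
]

_MAD_TO_SD = 0.6745  # Phi^{-1}(0.75): MAD of a Gaussian in SD units
_VAR_FLOOR = 1e-12


@dataclass
class SubbandPyramid:
    """Separable 2D wavelet pyramid: J detail levels plus the coarsest LL.

    ``levels[0]`` is the finest level (j = 1); each entry is a dict with
    keys ``"lh"``, ``"hl"``, ``"hh"``.  Only the LL band is recursively
    decomposed, so level j holds the detail bands LH^j / HL^j / HH^j.
    """

    levels: list[dict[str, np.ndarray]]
    ll_coarse: np.ndarray
    wavelet_name: str
    mode: str = "symmetric"
    original_shape: tuple[int, ...] | None = None

    @property
    def J(self) -> int:
        return len(self.levels)

    @property
    def M_per_subband(self) -> list[dict[str, int]]:
        return [{k: v.size for k, v in lev.items()} for lev in self.levels]


@dataclass(frozen=True)
class SubbandStats:
    """Noise / signal standard deviations and Laplace parameters of a subband."""

    sigma_n: float
    sigma_f: float
    sigma_g: float
    s: float
    v: float = 1.0


@dataclass(frozen=True)
class ThresholdSchedule:
    """Per-level gates T_j = a_j sigma_n sqrt(2 ln M) with a_j = 2^(J-j+1)."""

    T: np.ndarray  # T[j-1] is the threshold for level j (finest j = 1)
    a: np.ndarray
    J: int


@dataclass(frozen=True)
class BilateralParams:
    """Bilateral-filter kernel widths.

    sigma_d : spatial (domain) Gaussian SD in voxels.
    sigma_r : range Gaussian SD in intensity units.
    window_radius : half-width of the neighborhood; defaults to
        ``2 * ceil(sigma_d)``.
    """

    sigma_d: float = 2.0
    sigma_r: float = 0.1
    window_radius: int | None = None

    def __post_init__(self) -> None:
        if self.sigma_d <= 0 or self.sigma_r <= 0:
            raise ValueError("kernel widths must be positive")
        if self.window_radius is not None and self.window_radius < 1:
            raise ValueError("window_radius must be >= 1")

    @property
    def radius(self) -> int:
        if self.window_radius is not None:
            return int(self.window_radius)
        return int(2 * math.ceil(self.sigma_d))


def log_transform(image: np.ndarray, epsilon: float = 1e-3) -> np.ndarray:
    """Return ln(image + epsilon); epsilon admits zero-valued voxels."""
    image = np.asarray(image, dtype=float)
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if np.any(image < 0):
        raise ValueError("image intensities must be non-negative")
    return np.log(image + epsilon)


def inverse_log_transform(image: np.ndarray, epsilon: float = 1e-3) -> np.ndarray:
    """Inverse of :func:`log_transform`: exp(image) - epsilon."""
    return np.exp(np.asarray(image, dtype=float)) - epsilon


def decompose(image: np.ndarray, wavelet_name: str = "db4", J: int = 3) -> SubbandPyramid:
    """J-level separable 2D wavelet decomposition (LL recursed at each level)."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("decompose expects a 2D image (volumes are handled slice-wise)")
    if J < 1:
        raise ValueError("J must be >= 1")
    if min(image.shape) < 2**J:
        raise ValueError(f"image sides {image.shape} too small for J={J} levels")
    coeffs = pywt.wavedec2(image, wavelet_name, mode="symmetric", level=J)
    ll = coeffs[0]
    # pywt orders details coarsest-first; store finest-first (j = 1 ... J)
    levels = [
        {"lh": cH, "hl": cV, "hh": cD} for (cH, cV, cD) in reversed(coeffs[1:])
    ]
    return SubbandPyramid(
        levels=levels,
        ll_coarse=ll,
        wavelet_name=wavelet_name,
        original_shape=image.shape,
    )


def reconstruct(pyramid: SubbandPyramid) -> np.ndarray:
    """Inverse transform of a (possibly modified) pyramid."""
    coeffs = [pyramid.ll_coarse] + [
        (lev["lh"], lev["hl"], lev["hh"]) for lev in reversed(pyramid.levels)
    ]
    out = pywt.waverec2(coeffs, pyramid.wavelet_name, mode=pyramid.mode)
    if pyramid.original_shape is not None:
        out = out[tuple(slice(0, n) for n in pyramid.original_shape)]
    return out


def estimate_sigma_n(pyramid: SubbandPyramid) -> float:
    """Robust noise-SD estimate: median(|HH^1|) / 0.6745 on the finest diagonal band."""
    if pyramid.J < 1:
        raise ValueError("pyramid must have at least one level")
    hh1 = pyramid.levels[0]["hh"]
    return float(np.median(np.abs(hh1)) / _MAD_TO_SD)


def threshold_value(sigma_n: float, M: int, j: int, J: int) -> float:
    """T_j = 2^(J-j+1) * sigma_n * sqrt(2 ln M) for one level j."""
    if M < 1:
        raise ValueError("M must be >= 1")
    if sigma_n < 0:
        raise ValueError("sigma_n must be >= 0")
    return float(2.0 ** (J - j + 1) * sigma_n * math.sqrt(2.0 * math.log(M)))


def threshold_schedule(sigma_n: float, M: int, J: int) -> ThresholdSchedule:
    """Level-adaptive threshold schedule for levels j = 1 (finest) ... J."""
    if J < 1:
        raise ValueError("J must be >= 1")
    a = np.array([2.0 ** (J - j + 1) for j in range(1, J + 1)])
    T = np.array([threshold_value(sigma_n, M, j, J) for j in range(1, J + 1)])
    return ThresholdSchedule(T=T, a=a, J=J)


def estimate_laplace_scale(
    subband: np.ndarray, sigma_n: float, floor: float = _VAR_FLOOR
) -> float:
    """Moment-matched Laplace scale of the noise-free signal in a subband.

    var(observed) = sigma_g^2 + sigma_n^2 and Laplace variance = 2 s^2,
    so s = sqrt(max(var - sigma_n^2, floor) / 2), clamped positive.
    """
    subband = np.asarray(subband, dtype=float)
    if subband.size == 0:
        raise ValueError("subband must be non-empty")
    var_g = max(float(np.var(subband)) - sigma_n**2, floor)
    return math.sqrt(var_g / 2.0)


def shrink(
    f: np.ndarray | float, T_j: float, sigma_n: float, s: float
) -> np.ndarray | float:
    """Gated MAP shrinkage: 0 for |f| <= T_j, else sign(f) max(|f| - sigma_n^2/s, 0).

    The gate is non-strict (a coefficient exactly at threshold is
    zeroed).  Applied elementwise; odd, non-expansive and idempotent.
    """
    if s <= 0:
        raise ValueError("s must be positive")
    if T_j < 0:
        raise ValueError("T_j must be >= 0")
    arr = np.asarray(f, dtype=float)
    mag = np.abs(arr)
    soft = np.sign(arr) * np.maximum(mag - sigma_n**2 / s, 0.0)
    out = np.where(mag <= T_j, 0.0, soft)
    if np.isscalar(f) or arr.ndim == 0:
        return float(out)
    return out


def bilateral(image: np.ndarray, params: BilateralParams) -> np.ndarray:
    """Edge-preserving bilateral filter.

    h(x) = k(x)^-1 * sum_{xi in Omega(x)} f(xi) c(xi, x) s(f(xi), f(x))
    with Gaussian domain kernel c = exp(-||xi - x||^2 / 2 sigma_d^2) and
    range kernel s = exp(-(f(xi) - f(x))^2 / 2 sigma_r^2), normalized to
    unit DC gain; symmetric boundary padding.  Works for any ndim.
    """
    image = np.asarray(image, dtype=float)
    R = params.radius
    if any(n < 1 for n in image.shape):
        raise ValueError("empty image")
    padded = np.pad(image, R, mode="symmetric")
    num = np.zeros_like(image)
    den = np.zeros_like(image)
    inv2sd = 1.0 / (2.0 * params.sigma_d**2)
    inv2sr = 1.0 / (2.0 * params.sigma_r**2)
    for offset in np.ndindex(*([2 * R + 1] * image.ndim)):
        off = np.array(offset) - R
        shifted = padded[tuple(slice(R + o, R + o + n) for o, n in zip(off, image.shape))]
        w = math.exp(-float(off @ off) * inv2sd) * np.exp(
            -((shifted - image) ** 2) * inv2sr
        )
        num += shifted * w
        den += w
    return num / den


def subband_stats(subband: np.ndarray, sigma_n: float) -> SubbandStats:
    """Observed / noise-free SDs and the Laplace scale for one subband."""
    sigma_f = float(np.std(subband))
    s = estimate_laplace_scale(subband, sigma_n)
    sigma_g = s * math.sqrt(2.0)
    return SubbandStats(sigma_n=sigma_n, sigma_f=sigma_f, sigma_g=sigma_g, s=s)


def _denoise_slice(
    image: np.ndarray,
    wavelet_name: str,
    J: int,
    bilateral_params: BilateralParams | None,
    epsilon: float,
    apply_log: bool,
    sigma_n: float | None,
    stats_log: list | None = None,
) -> np.ndarray:
    work = log_transform(image, epsilon) if apply_log else np.asarray(image, dtype=float)
    pyr = decompose(work, wavelet_name, J)
    sn = estimate_sigma_n(pyr) if sigma_n is None else float(sigma_n)

    for j, lev in enumerate(pyr.levels, start=1):
        for name in ("lh", "hl", "hh"):
            band = lev[name]
            st = subband_stats(band, sn)
            T_j = threshold_value(sn, band.size, j, J)
            lev[name] = shrink(band, T_j, sn, st.s)
            if stats_log is not None:
                stats_log.append(
                    {
                        "level": j,
                        "subband": name,
                        "M": band.size,
                        "T": T_j,
                        "sigma_n": st.sigma_n,
                        "sigma_f": st.sigma_f,
                        "sigma_g": st.sigma_g,
                        "s": st.s,
                    }
                )

    if bilateral_params is not None:
        pyr.ll_coarse = bilateral(pyr.ll_coarse, bilateral_params)

    out = reconstruct(pyr)
    if apply_log:
        out = inverse_log_transform(out, epsilon)
        out = np.maximum(out, 0.0)
    return out


def denoise_image(
    image: np.ndarray,
    wavelet_name: str = "db4",
    J: int = 3,
    bilateral_params: BilateralParams | None = BilateralParams(),
    epsilon: float = 1e-3,
    apply_log: bool = True,
    sigma_n: float | None = None,
    stats_log: list | None = None,
) -> np.ndarray:
    """Full denoising chain; 3D volumes are processed slice-by-slice.

    Parameters
    ----------
    image
        2D image or 3D volume (first axis = slices), non-negative when
        ``apply_log`` is set.
    wavelet_name, J
        Analysis wavelet and decomposition depth.
    bilateral_params
        Parameters for the LL-band bilateral filter; ``None`` disables it.
    epsilon
        Offset of the log transform.
    apply_log
        Skip the log/exp envelope for images that are not
        speckle-corrupted (directly acquired volumes).
    sigma_n
        Override the MAD noise estimate (0 disables shrinkage entirely).
    stats_log
        Optional list that receives one dict of estimated statistics per
        shrunk subband.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        return _denoise_slice(
            image, wavelet_name, J, bilateral_params, epsilon, apply_log, sigma_n, stats_log
        )
    if image.ndim == 3:
        return np.stack(
            [
                _denoise_slice(
                    sl, wavelet_name, J, bilateral_params, epsilon, apply_log, sigma_n, stats_log
                )
                for sl in image
            ]
        )
    raise ValueError("image must be 2D or 3D")
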