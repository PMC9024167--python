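"""Evaluation criteria: SSIM, SNR, relative overlap, region accuracy.

SSIM is the exponent-weighted product l^alpha * c^beta * s^gamma of the
standard luminance / contrast / structure comparisons over a sliding
Gaussian window.  ``relative_overlap`` is the Jaccard index |T∩S|/|T∪S|.
``accuracy_eq20`` is |T∩S|/|S| — the precision of the segmented region
against the reference region; the conventional per-voxel accuracy is
available separately as :func:`pixel_accuracy`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "MetricReport",
    "ssim",
    "snr_db",
    "relative_overlap",
    "accuracy_eq20",
    "pixel_accuracy",
    "dice",
]


@dataclass(frozen=True)
class MetricReport:
    """Metric bundle for one (prediction, reference) pair."""

    ssim: float
    snr_db: float
    r_overlap: float
    accuracy: float

    def as_dict(self) -> dict[str, float]:
        return {
            "ssim": self.ssim,
            "snr_db": self.snr_db,
            "r_overlap": self.r_overlap,
            "accuracy": self.accuracy,
        }


def _check_same_shape(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def ssim(
    X: np.ndarray,
    Y: np.ndarray,
    alpha: float = 1.0,
    beta: float = 1.0,
    gamma: float = 1.0,
    window: int = 7,
    sigma: float = 1.5,
    K1: float = 0.01,
    K2: float = 0.03,
    data_range: float | None = None,
) -> float:
    """Structural similarity between images ``X`` and ``Y``.

    Windowed means/variances/covariance are computed with a Gaussian
    kernel of SD ``sigma`` truncated to ``window``; the three comparison
    maps are combined as l^alpha * c^beta * s^gamma with the usual
    stabilizers C1 = (K1 L)^2, C2 = (K2 L)^2, C3 = C2/2 (L = dynamic
    range of the reference ``X`` unless given), and averaged over the
    interior (the half-window border is cropped).
    """
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    _check_same_shape(X, Y)
    if min(alpha, beta, gamma) < 0:
        raise ValueError("exponents must be >= 0")
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")

    if data_range is None:
        data_range = float(X.max() - X.min())
        if data_range == 0:
            data_range = 1.0
    C1 = (K1 * data_range) ** 2
    C2 = (K2 * data_range) ** 2
    C3 = C2 / 2.0

    pad = (window - 1) // 2
    truncate = pad / sigma

    def filt(a: np.ndarray) -> np.ndarray:
        return ndimage.gaussian_filter(a, sigma=sigma, truncate=truncate)

    ux, uy = filt(X), filt(Y)
    vx = np.clip(filt(X * X) - ux * ux, 0.0, None)
    vy = np.clip(filt(Y * Y) - uy * uy, 0.0, None)
    vxy = filt(X * Y) - ux * uy
    sx, sy = np.sqrt(vx), np.sqrt(vy)

    lum = (2 * ux * uy + C1) / (ux**2 + uy**2 + C1)
    con = (2 * sx * sy + C2) / (vx + vy + C2)
    struct = (vxy + C3) / (sx * sy + C3)

    smap = np.sign(lum) * np.abs(lum) ** alpha
    smap = smap * np.sign(con) * np.abs(con) ** beta
    smap = smap * np.sign(struct) * np.abs(struct) ** gamma

    interior = tuple(slice(pad, n - pad) for n in X.shape)
    return float(smap[interior].mean())


def snr_db(signal: np.ndarray, noisy: np.ndarray) -> float:
    """Signal-to-noise ratio 10*log10(sum signal^2 / sum (noisy - signal)^2) in dB.

    A zero residual (``noisy == signal``) returns ``inf``.
    """
    signal = np.asarray(signal, dtype=np.float64)
    noisy = np.asarray(noisy, dtype=np.float64)
    _check_same_shape(signal, noisy)
    resid_power = float(np.sum((noisy - signal) ** 2))
    if resid_power == 0.0:
        return float("inf")
    return float(10.0 * np.log10(np.sum(signal**2) / resid_power))


def _as_bool(mask: np.ndarray) -> np.ndarray:
    return np.asarray(mask).astype(bool)


def relative_overlap(T: np.ndarray, S: np.ndarray) -> float:
    """Jaccard index |T∩S| / |T∪S|; 0 when both masks are empty."""
    T, S = _as_bool(T), _as_bool(S)
    _check_same_shape(T, S)
    union = int(np.sum(T | S))
    if union == 0:
        return 0.0
    return float(np.sum(T & S) / union)


def accuracy_eq20(T: np.ndarray, S: np.ndarray) -> float:
    """Region accuracy |T∩S| / |S| (precision of the segmented region S)."""
    T, S = _as_bool(T), _as_bool(S)
    _check_same_shape(T, S)
    n_s = int(np.sum(S))
    if n_s == 0:
        raise ValueError("segmented region S is empty; accuracy undefined")
    return float(np.sum(T & S) / n_s)


def pixel_accuracy(T: np.ndarray, S: np.ndarray) -> float:
    """Conventional per-voxel accuracy (TP + TN) / total."""
    T, S = _as_bool(T), _as_bool(S)
    _check_same_shape(T, S)
    return float(np.mean(T == S))


def dice(T: np.ndarray, S: np.ndarray) -> float:
    """Dice coefficient 2|T∩S| / (|T| + |S|); 1.0 when both masks are empty."""
    T, S = _as_bool(T), _as_bool(S)
    _check_same_shape(T, S)
    denom = int(np.sum(T)) + int(np.sum(S))
    if denom == 0:
        return 1.0
    return float(2.0 * np.sum(T & S) / denom)
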