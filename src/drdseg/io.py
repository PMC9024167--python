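"""Readers and writers for NIfTI and PNG images, plus the pipeline config.

Intensities are floating point on read; 8-bit PNGs are normalized by 255
(and 16-bit by 65535) so a saturated pixel maps to 1.0.  A directory of
PNGs is assembled into a volume in filename sort order.  Masks are
written as unsigned 8-bit {0, 1} NIfTI (or 0/255 PNG); probability maps
as 32-bit float NIfTI.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import yaml

__all__ = ["Image", "read_image", "write_image", "write_mask", "PipelineConfig"]

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_PNG_SUFFIXES = (".png",)


@dataclass(frozen=True)
class Image:
    """Scalar grid with voxel-spacing metadata (mm per voxel, one per axis)."""

    data: np.ndarray
    spacing: tuple[float, ...]


def _is_nifti(path: Path) -> bool:
    return path.name.endswith(".nii") or path.name.endswith(".nii.gz")


def read_image(path) -> Image:
    """Read a NIfTI file, a PNG, or a directory of PNG slices."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    if path.is_dir():
        slices = sorted(p for p in path.iterdir() if p.suffix.lower() in _PNG_SUFFIXES)
        if not slices:
            raise ValueError(f"directory {path} contains no PNG slices")
        stack = np.stack([_read_png(p) for p in slices])
        return Image(data=stack, spacing=(1.0,) * stack.ndim)
    if _is_nifti(path):
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        spacing = tuple(float(z) for z in img.header.get_zooms()[: data.ndim])
        return Image(data=data, spacing=spacing)
    if path.suffix.lower() in _PNG_SUFFIXES:
        data = _read_png(path)
        return Image(data=data, spacing=(1.0,) * data.ndim)
    raise ValueError(f"unsupported image format: {path} (use NIfTI or PNG)")


def _read_png(path: Path) -> np.ndarray:
    raw = iio.imread(path)
    if raw.ndim == 3:  # RGB(A): luminance of the first three channels
        raw = raw[..., :3].mean(axis=-1)
    if raw.dtype == np.uint8:
        return raw.astype(float) / 255.0
    if raw.dtype == np.uint16:
        return raw.astype(float) / 65535.0
    return raw.astype(float)


def write_image(data: np.ndarray, path, spacing: tuple[float, ...] | None = None) -> Path:
    """Write a float image as NIfTI (float32) or PNG (uint8, [0,1] clipped)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.asarray(data)
    if _is_nifti(path):
        affine = np.diag(list(spacing or (1.0,) * data.ndim) + [1.0])[: data.ndim + 1, : data.ndim + 1]
        full_affine = np.eye(4)
        full_affine[: affine.shape[0] - 1, : affine.shape[1] - 1] = affine[:-1, :-1]
        nib.save(nib.Nifti1Image(data.astype(np.float32), full_affine), str(path))
    elif path.suffix.lower() in _PNG_SUFFIXES:
        if data.ndim != 2:
            raise ValueError("PNG output requires a 2D image")
        iio.imwrite(path, (np.clip(data, 0.0, 1.0) * 255).round().astype(np.uint8))
    else:
        raise ValueError(f"unsupported output format: {path}")
    return path


def write_mask(mask: np.ndarray, path, spacing: tuple[float, ...] | None = None) -> Path:
    """Write a binary mask: uint8 {0,1} NIfTI or 0/255 PNG."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    mask = np.asarray(mask).astype(np.uint8)
    if _is_nifti(path):
        full_affine = np.eye(4)
        for i, z in enumerate(spacing or (1.0,) * mask.ndim):
            if i < 3:
                full_affine[i, i] = z
        nib.save(nib.Nifti1Image(mask, full_affine), str(path))
    elif path.suffix.lower() in _PNG_SUFFIXES:
        if mask.ndim != 2:
            raise ValueError("PNG output requires a 2D mask")
        iio.imwrite(path, (mask * 255).astype(np.uint8))
    else:
        raise ValueError(f"unsupported output format: {path}")
    return path


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SimulateConfig:
    shape: tuple[int, ...] = (84, 84)
    n_lesions: int = 2
    contrast: float = 0.4
    noise_model: str = "multiplicative_speckle"
    noise_sigma: float = 0.2


@dataclass
class InputConfig:
    image: str | None = None
    mask: str | None = None


@dataclass
class DenoiseConfig:
    enabled: bool = True
    wavelet: str = "db4"
    levels: int = 3
    sigma_d: float = 2.0
    sigma_r: float = 0.1
    epsilon: float = 1e-3
    apply_log: bool = True


@dataclass
class NetTrainConfig:
    depth: int = 2
    base_channels: int = 8
    gn_groups: int = 8
    dilation_rates: tuple[int, int, int, int] = (3, 5, 7, 9)
    deep_supervision: bool = False
    use_3d: bool = False
    train_steps: int = 150
    lr: float = 3e-3
    checkpoint: str | None = None


@dataclass
class RefineConfig:
    kappa: float = 0.9
    t_max: int = 64
    delta: float = 0.05
    chi: float = 0.0
    initial_threshold: float = 0.5


@dataclass
class PipelineConfig:
    """Full pipeline configuration; round-trips losslessly through YAML."""

    seed: int = 7
    out_dir: str = "out"
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    input: InputConfig = field(default_factory=InputConfig)
    denoise: DenoiseConfig = field(default_factory=DenoiseConfig)
    net: NetTrainConfig = field(default_factory=NetTrainConfig)
    refine: RefineConfig = field(default_factory=RefineConfig)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        return _strict_build(cls, raw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulate"]["shape"] = list(d["simulate"]["shape"])
        d["net"]["dilation_rates"] = list(d["net"]["dilation_rates"])
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


_TUPLE_FIELDS = {"shape", "dilation_rates"}


def _strict_build(cls, raw: dict):
    """Build a dataclass from a dict, rejecting unknown keys recursively."""
    if not isinstance(raw, dict):
        raise ValueError(f"expected a mapping for {cls.__name__}, got {type(raw).__name__}")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(raw) - set(fields)
    if unknown:
        raise ValueError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for name, value in raw.items():
        f = fields[name]
        factory = f.default_factory if f.default_factory is not dataclasses.MISSING else None
        if factory is not None and dataclasses.is_dataclass(factory):
            kwargs[name] = _strict_build(factory, value)
        elif name in _TUPLE_FIELDS and isinstance(value, (list, tuple)):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)
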