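"""DRD U-Net assembly: residual encoder-decoder with a dilated context bottleneck.

The network is U-shaped: residual blocks (two convolution layers each)
per level, 2x max-pool downsampling, the 4-branch dilated context module
at the bottleneck, nearest-upsample + convolution decoding with skip
connections, and a 1-channel sigmoid head producing per-voxel foreground
probabilities.  ``use_3d`` switches every convolution to 3x3x3 for
volumetric inputs.  Optional deep supervision attaches auxiliary sigmoid
heads to intermediate decoder levels; they contribute to the training
loss only.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .autodiff import Tensor, concat, maxpool2, upsample2
from .blocks import Conv, ContextModule, Module, ResidualUnit

__all__ = ["NetConfig", "UNet", "build_network", "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class NetConfig:
    """Architecture hyper-parameters.

    depth : number of resolution levels (depth - 1 poolings).
    base_channels : channels at the finest level; doubled per level.
    dilation_rates : the four context-branch dilation rates.
    gn_groups : group count for group normalization; must divide every
        normalized channel count (i.e. ``base_channels``).
    use_3d : build 3x3x3 convolutions for volumetric input.
    deep_supervision : attach auxiliary heads to decoder levels.
    """

    depth: int = 3
    base_channels: int = 16
    dilation_rates: tuple[int, int, int, int] = (3, 5, 7, 9)
    gn_groups: int = 8
    use_3d: bool = False
    deep_supervision: bool = False
    in_channels: int = 1

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if len(self.dilation_rates) != 4:
            raise ValueError("dilation_rates must have exactly 4 entries")
        if self.base_channels % self.gn_groups != 0:
            raise ValueError("gn_groups must divide base_channels")
        if self.base_channels % 4 != 0:
            raise ValueError("base_channels must be divisible by 4 (context module)")


class UNet(Module):
    """Residual U-Net with an atrous-pyramid bottleneck."""

    def __init__(self, config: NetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        nd = 3 if config.use_3d else 2
        self.nd = nd
        c = config.base_channels
        g = config.gn_groups

        self.encoders: list[ResidualUnit] = []
        ch = config.in_channels
        enc_channels = []
        for lvl in range(config.depth - 1):
            out = c * 2**lvl
            self.encoders.append(
                ResidualUnit(ch, out, nd=nd, gn_groups=g, shortcut="project", rng=rng)
            )
            enc_channels.append(out)
            ch = out

        bott = c * 2 ** (config.depth - 1)
        self.bottleneck = ResidualUnit(ch, bott, nd=nd, gn_groups=g, shortcut="project", rng=rng)
        self.context = ContextModule(bott, rates=config.dilation_rates, nd=nd, rng=rng)

        self.up_convs: list[Conv] = []
        self.decoders: list[ResidualUnit] = []
        ch = bott
        for lvl in reversed(range(config.depth - 1)):
            skip = enc_channels[lvl]
            self.up_convs.append(Conv(ch, skip, 3, nd=nd, rng=rng))
            self.decoders.append(
                ResidualUnit(2 * skip, skip, nd=nd, gn_groups=g, shortcut="project", rng=rng)
            )
            ch = skip

        self.head = Conv(ch, 1, 1, nd=nd, rng=rng)
        self.aux_heads: list[Conv] = []
        if config.deep_supervision:
            # one auxiliary head per intermediate decoder level (coarse to fine)
            for lvl in reversed(range(1, config.depth - 1)):
                self.aux_heads.append(Conv(c * 2**lvl, 1, 1, nd=nd, rng=rng))

    # -----------------------------------------------------------------
    def _check_input(self, x: Tensor) -> None:
        nd = self.nd
        if x.ndim != nd + 2:
            raise ValueError(
                f"expected (N, C, {'D, H, W' if nd == 3 else 'H, W'}) input, got shape {x.shape}"
            )
        factor = 2 ** (self.config.depth - 1)
        for s in x.shape[2:]:
            if s % factor:
                raise ValueError(
                    f"spatial dims {x.shape[2:]} must be divisible by {factor} "
                    f"(depth {self.config.depth})"
                )

    def forward_logits(self, x: Tensor):
        """Pre-sigmoid head output plus any auxiliary-head logit maps."""
        self._check_input(x)
        skips = []
        for enc in self.encoders:
            x = enc(x)
            skips.append(x)
            x = maxpool2(x)
        x = self.context(self.bottleneck(x))
        aux_out: list[Tensor] = []
        for k, (up, dec) in enumerate(zip(self.up_convs, self.decoders)):
            x = up(upsample2(x))
            x = dec(concat([x, skips[-(k + 1)]], axis=1))
            if self.aux_heads and k < len(self.up_convs) - 1:
                aux_out.append(self.aux_heads[k](x))
        return self.head(x), aux_out

    def forward(self, x: Tensor, return_aux: bool = False):
        """Per-voxel foreground probabilities; optionally the aux-head maps too."""
        logit, aux_logits = self.forward_logits(x)
        prob = logit.sigmoid()
        if return_aux:
            return prob, [a.sigmoid() for a in aux_logits]
        return prob

    def predict(self, images: np.ndarray, batch_first: bool = True) -> np.ndarray:
        """Forward a numpy batch (N, H, W[, D]) or single image; returns probabilities."""
        arr = np.asarray(images, dtype=float)
        single = arr.ndim == self.nd
        if single:
            arr = arr[None]
        x = Tensor(arr[:, None])
        prob = self.forward(x).data[:, 0]
        return prob[0] if single else prob

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


def build_network(config: NetConfig, seed: int = 0) -> UNet:
    """Construct the network from a validated config with seeded initialization."""
    return UNet(config, seed=seed)


def save_checkpoint(net: UNet, path) -> None:
    """Store config + weights in an ``.npz`` archive."""
    cfg = asdict(net.config)
    cfg["dilation_rates"] = list(cfg["dilation_rates"])
    arrays = {f"param_{i}": p.data for i, p in enumerate(net.parameters())}
    np.savez(path, config=json.dumps(cfg), **arrays)


def load_checkpoint(path) -> UNet:
    """Rebuild a network from :func:`save_checkpoint` output."""
    with np.load(path, allow_pickle=False) as archive:
        cfg = json.loads(str(archive["config"]))
        cfg["dilation_rates"] = tuple(cfg["dilation_rates"])
        net = UNet(NetConfig(**cfg))
        params = net.parameters()
        for i, p in enumerate(params):
            stored = archive[f"param_{i}"]
            if stored.shape != p.data.shape:
                raise ValueError("checkpoint does not match the configured architecture")
            p.data = stored.astype(np.float64)
    return net
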