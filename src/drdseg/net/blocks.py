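"""Building blocks: convolution, group normalization, residual units, ASPP context.

A residual unit computes m = h(b) + I(b, w): shortcut h is the identity
(or a 1x1 projection when the channel count changes) and the residual
branch I is conv -> GroupNorm -> ReLU -> conv.  The multiscale context
module is a 4-branch atrous spatial pyramid: parallel dilated
convolutions (default rates 3, 5, 7, 9) each map 4c -> c channels and
their outputs are concatenated back to 4c channels at unchanged spatial
size.  Group normalization (channels split into groups, normalized per
sample) replaces batch normalization so behavior is batch-size
independent.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, convnd

__all__ = ["Conv", "GroupNorm", "ResidualUnit", "ContextModule", "stack_residuals"]


class Module:
    """Tiny base: parameter collection and call syntax."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)


class Conv(Module):
    """Stride-1 "same" convolution, odd kernel, optional dilation.

    He-normal weight init from the given generator; ``zero_init`` zeroes
    weights and bias (used to make residual branches exact identities).
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        nd: int = 2,
        dilation: int = 1,
        bias: bool = True,
        rng: np.random.Generator | None = None,
        zero_init: bool = False,
    ):
        rng = rng or np.random.default_rng(0)
        kshape = (out_channels, in_channels) + (kernel_size,) * nd
        fan_in = in_channels * kernel_size**nd
        if zero_init:
            w = np.zeros(kshape)
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=kshape)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True) if bias else None
        self.dilation = dilation

    def forward(self, x: Tensor) -> Tensor:
        return convnd(x, self.weight, self.bias, dilation=self.dilation)


class GroupNorm(Module):
    """Normalize each sample over channel groups; learnable scale and shift."""

    def __init__(self, channels: int, groups: int = 8, eps: float = 1e-5):
        if channels % groups != 0:
            raise ValueError(f"groups ({groups}) must divide channels ({channels})")
        self.groups = groups
        self.channels = channels
        self.eps = eps
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        n, c = x.shape[:2]
        spatial = x.shape[2:]
        if c != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {c}")
        g = self.groups
        xg = x.reshape(n, g, -1)
        mu = xg.mean(axis=2, keepdims=True)
        centered = xg - mu
        var = (centered * centered).mean(axis=2, keepdims=True)
        xn = centered * ((var + self.eps) ** -0.5)
        xn = xn.reshape(n, c, *spatial)
        shape = (1, c) + (1,) * len(spatial)
        return xn * self.gamma.reshape(*shape) + self.beta.reshape(*shape)


class ResidualUnit(Module):
    """m = h(b) + I(b, w) with I = conv -> GN -> ReLU -> conv.

    ``shortcut`` is ``"identity"`` (requires matching channel counts) or
    ``"project"`` (1x1 convolution).
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        nd: int = 2,
        gn_groups: int = 8,
        shortcut: str = "identity",
        rng: np.random.Generator | None = None,
        zero_init: bool = False,
    ):
        if shortcut not in ("identity", "project"):
            raise ValueError("shortcut must be 'identity' or 'project'")
        if shortcut == "identity" and in_channels != out_channels:
            raise ValueError(
                f"identity shortcut needs matching channels, got {in_channels} -> "
                f"{out_channels}; configure a 1x1 projection"
            )
        rng = rng or np.random.default_rng(0)
        self.conv1 = Conv(in_channels, out_channels, 3, nd=nd, rng=rng, zero_init=zero_init)
        self.norm = GroupNorm(out_channels, gn_groups)
        self.conv2 = Conv(out_channels, out_channels, 3, nd=nd, rng=rng, zero_init=zero_init)
        self.proj = (
            Conv(in_channels, out_channels, 1, nd=nd, rng=rng) if shortcut == "project" else None
        )

    def branch(self, x: Tensor) -> Tensor:
        """The learned transform I(b, w)."""
        return self.conv2(self.norm(self.conv1(x)).relu())

    def shortcut_map(self, x: Tensor) -> Tensor:
        """h(b): identity or the 1x1 projection."""
        return x if self.proj is None else self.proj(x)

    def forward(self, x: Tensor) -> Tensor:
        return self.shortcut_map(x) + self.branch(x)


def stack_residuals(x: Tensor, units: list[ResidualUnit]) -> Tensor:
    """Apply residual units in sequence.

    For identity-shortcut units this telescopes to
    b_N = b_n + sum_i F(b_i, W_i).
    """
    for unit in units:
        x = unit(x)
    return x


class ContextModule(Module):
    """4-branch dilated (atrous) spatial pyramid over a 4c-channel input.

    Each branch is a 3^nd convolution with dilation rate r_i mapping
    4c -> c channels at unchanged spatial size (padding = dilation); the
    four outputs are concatenated back to 4c channels.  A 3-tap kernel
    at rate r spans a receptive field of 2r + 1 voxels per axis.
    """

    def __init__(
        self,
        channels: int,
        rates: tuple[int, int, int, int] = (3, 5, 7, 9),
        nd: int = 2,
        rng: np.random.Generator | None = None,
        zero_init: bool = False,
        bias: bool = True,
    ):
        if len(rates) != 4:
            raise ValueError("exactly 4 dilation rates are required")
        if channels % 4 != 0:
            raise ValueError(f"input channels ({channels}) must be divisible by 4")
        rng = rng or np.random.default_rng(0)
        c = channels // 4
        self.rates = tuple(int(r) for r in rates)
        self.branches = [
            Conv(channels, c, 3, nd=nd, dilation=r, rng=rng, zero_init=zero_init, bias=bias)
            for r in self.rates
        ]

    def forward(self, x: Tensor) -> Tensor:
        return concat([b(x) for b in self.branches], axis=1)
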