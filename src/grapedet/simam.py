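"""SimAM: parameter-free attention from a per-pixel minimal-energy function.

Each activation ``t`` in a channel is scored by how linearly separable it is
from the other activations of the same channel.  With channel mean ``mu`` and
population variance ``s2`` (computed over all ``M = H*W`` pixels), the closed
form of that minimal energy is

    e*(t) = 4 (s2 + lam) / ((t - mu)^2 + 2 s2 + 2 lam)

so distinctive pixels (large ``|t - mu|``) have *low* energy.  The refined
feature is ``sigmoid(1/e*) * x`` — a full 3-D reweighting that adds no
learnable parameters.  ``lam`` regularizes the energy; 1e-4 is the published
default.

Statistics are per channel and per sample; the mean and variance include the
target pixel itself (no leave-one-out correction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor

__all__ = ["SimAMConfig", "channel_statistics", "minimal_energy_map", "simam_refine", "SimAM"]


@dataclass(frozen=True)
class SimAMConfig:
    lam: float = 1e-4

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lam must be > 0")


def channel_statistics(channel: np.ndarray) -> tuple[float, float]:
    """Mean and population (1/M) variance of one channel's activations."""
    channel = np.asarray(channel, dtype=np.float64)
    if channel.size < 2:
        raise ValueError("channel needs at least 2 pixels for a defined variance")
    if not np.all(np.isfinite(channel)):
        raise ValueError("channel contains non-finite values")
    return float(channel.mean()), float(channel.var())


def minimal_energy_map(channel: np.ndarray, cfg: SimAMConfig = SimAMConfig()) -> np.ndarray:
    """Elementwise minimal energy e*(t) of one channel.

    A constant channel has s2 = 0 and (t - mu) = 0 everywhere, forcing
    e* = 4 lam / (2 lam) = 2 regardless of lam.
    """
    mu, s2 = channel_statistics(channel)
    t = np.asarray(channel, dtype=np.float64)
    return 4.0 * (s2 + cfg.lam) / ((t - mu) ** 2 + 2.0 * s2 + 2.0 * cfg.lam)


def simam_refine(feature: np.ndarray, cfg: SimAMConfig = SimAMConfig()) -> np.ndarray:
    """Refine an ``(C, H, W)`` or ``(N, C, H, W)`` feature map with SimAM.

    Pure-numpy reference used by tests and available for post-hoc analysis;
    the in-graph layer is :class:`SimAM`.
    """
    feature = np.asarray(feature, dtype=np.float64)
    single = feature.ndim == 3
    x = feature[None] if single else feature
    n, c, h, w = x.shape
    if h * w < 2:
        warnings.warn("spatial size 1x1: SimAM variance undefined, passing through")
        return feature
    mu = x.mean(axis=(2, 3), keepdims=True)
    s2 = x.var(axis=(2, 3), keepdims=True)
    e_star = 4.0 * (s2 + cfg.lam) / ((x - mu) ** 2 + 2.0 * s2 + 2.0 * cfg.lam)
    out = x / (1.0 + np.exp(-1.0 / e_star))
    return out[0] if single else out


class SimAM(nn.Module):
    """Differentiable SimAM layer (zero parameters)."""

    def __init__(self, cfg: SimAMConfig = SimAMConfig()):
        super().__init__()
        self.cfg = cfg

    def forward(self, x: Tensor) -> Tensor:
        h, w = x.shape[2], x.shape[3]
        if h * w < 2:
            warnings.warn("spatial size 1x1: SimAM variance undefined, passing through")
            return x
        mu = x.mean(axis=(2, 3), keepdims=True)
        centred = x - mu
        s2 = (centred * centred).mean(axis=(2, 3), keepdims=True)
        e_star = (4.0 * (s2 + self.cfg.lam)) / (centred * centred + 2.0 * s2 + 2.0 * self.cfg.lam)
        return x * nn.sigmoid(1.0 / e_star)
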