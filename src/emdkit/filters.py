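"""The correlator's low-pass / high-pass temporal filter pair.

Every estimator in the hierarchy consumes the same six filtered channels
(f*V1), (g*V1), (f*V2), (g*V2), (f*V3), (g*V3), where

    f(t) = t exp(-t/tau),  t >= 0        (low-pass)
    g(t) = df/dt = (1 - t/tau) exp(-t/tau)   (high-pass)

with tau = 20 ms.  The high-pass kernel integrates to zero, so g-channels
annihilate constants -- static scenes produce no motion signal.  Kernel
gain is not pinned down by the science (fitted weights absorb it), so f is
normalized to unit discrete sum, g is scaled by the same factor and then
mean-adjusted so its discrete sum is exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .ensemble import Ensemble, MotionClip

__all__ = [
    "FilterKernels",
    "FilteredBank",
    "make_kernels",
    "filter_bank",
    "bank_readout",
    "ensemble_readout",
    "CHANNEL_NAMES",
]

CHANNEL_NAMES = ("fV1", "gV1", "fV2", "gV2", "fV3", "gV3")


@dataclass(frozen=True)
class FilterKernels:
    tau: float
    dt: float
    f: np.ndarray
    g: np.ndarray


@dataclass(frozen=True)
class FilteredBank:
    """The filtered channels of one clip; models read the final time point."""

    channels: np.ndarray  # (2 * n_receptors, n_steps), ordered as CHANNEL_NAMES
    dt: float
    readout_index: int = -1

    def readout(self) -> np.ndarray:
        return self.channels[:, self.readout_index]


def make_kernels(tau: float = 0.020, dt: float = 0.005, support: float | None = None) -> FilterKernels:
    """Discretize f and g on the dt grid.

    ``support`` defaults to 10 tau and must be at least that long; shorter
    supports would clip a non-negligible kernel tail.  ``g`` is the analytic
    derivative sampled on the grid, then mean-adjusted to an exactly zero
    discrete sum.
    """
    if support is None:
        support = 10.0 * tau
    if dt >= tau:
        raise ValueError("dt must resolve the kernel: require dt < tau")
    if support < 10.0 * tau:
        raise ValueError("kernel support must be >= 10 tau")
    t = np.arange(int(np.ceil(support / dt)) + 1) * dt
    f = t * np.exp(-t / tau)
    scale = 1.0 / f.sum()
    f = f * scale
    g = (1.0 - t / tau) * np.exp(-t / tau) * scale
    g = g - g.sum() / g.size
    return FilterKernels(tau=tau, dt=dt, f=f, g=g)


def _causal(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    n_t = x.shape[-1]
    return fftconvolve(x, kernel.reshape((1,) * (x.ndim - 1) + (-1,)), axes=-1)[..., :n_t]


def filter_bank(clip: MotionClip, kernels: FilterKernels, dt: float | None = None) -> FilteredBank:
    """Causal convolution of each receptor signal with f and g.

    ``dt`` (if given) is checked against the kernel grid; a mismatch is an
    error because the discrete kernels are tied to their sampling step.
    """
    if dt is not None and not np.isclose(dt, kernels.dt):
        raise ValueError(f"clip grid {dt}s does not match kernel grid {kernels.dt}s")
    V = np.asarray(clip.V, dtype=float)
    n_rec, n_t = V.shape
    channels = np.empty((2 * n_rec, n_t))
    channels[0::2] = _causal(V, kernels.f)
    channels[1::2] = _causal(V, kernels.g)
    return FilteredBank(channels=channels, dt=kernels.dt)


def bank_readout(V: np.ndarray, kernels: FilterKernels) -> np.ndarray:
    """Filtered-channel values at the final time point only.

    ``V`` has shape ``(..., n_receptors, n_steps)``; the result has shape
    ``(..., 2 * n_receptors)`` ordered f1, g1, f2, g2, ...  Computing just
    the readout is a dot product with the reversed kernel tail, which is
    how large ensembles are filtered without materializing full series.
    """
    V = np.asarray(V, dtype=float)
    n_t = V.shape[-1]
    k = min(n_t, kernels.f.size)
    tail = V[..., n_t - k:]
    f_rev = kernels.f[:k][::-1]
    g_rev = kernels.g[:k][::-1]
    out = np.empty(V.shape[:-1] + (2,))
    out[..., 0] = tail @ f_rev
    out[..., 1] = tail @ g_rev
    return out.reshape(V.shape[:-2] + (-1,))


def ensemble_readout(ens: Ensemble, kernels: FilterKernels | None = None) -> np.ndarray:
    """Readout matrix (n_clips, 2 * n_receptors) for a whole ensemble."""
    if kernels is None:
        kernels = make_kernels(dt=ens.cfg.dt)
    if not np.isclose(ens.cfg.dt, kernels.dt):
        raise ValueError("ensemble and kernels are on different time grids")
    return bank_readout(ens.V, kernels)
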