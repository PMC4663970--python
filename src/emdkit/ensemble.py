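"""Photoreceptor responses to rigid translation and the naturalistic ensemble.

Each simulated "naturalistic motion" is one panorama, translated rigidly
at a constant velocity past three horizontally adjacent photoreceptors.
A photoreceptor's linear response is

    V_i(t) = integral dt' T(t') integral dx M(x - x_i) c(x - v (t - t')),

with M a Gaussian spatial acceptance (FWHM 5.7 deg) and T a causal
exponential temporal kernel (10 ms).  The ensemble pairs every motion with
its mirror image -- panorama reflected, velocity negated, receptors
relabeled 3-2-1 -- so that left-right symmetry holds exactly, not just in
distribution.

Discretization: the spatial integral is taken on the panorama's 1-degree
grid with the Gaussian sampled at pixel centers and renormalized; the
shifted panorama is evaluated with periodic linear interpolation; the
temporal integral is a causal discrete convolution on the 5-ms grid with
the exponential kernel normalized to unit sum, run from zero filter state
(the transient is inside the clip; models read out only its final sample).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np
from scipy.ndimage import convolve1d
from scipy.signal import fftconvolve

from .imagery import Image1D, _gaussian_kernel, _FWHM_TO_SIGMA

__all__ = [
    "PhotoreceptorConfig",
    "MotionClip",
    "Ensemble",
    "photoreceptor_response",
    "movie_response",
    "build_ensemble",
    "save_ensemble",
    "load_ensemble",
]


@dataclass(frozen=True)
class PhotoreceptorConfig:
    """Spatiotemporal front-end constants (degrees, seconds)."""

    spatial_fwhm: float = 5.7
    temporal_tau: float = 0.010
    spacing: float = 5.1
    n_receptors: int = 3
    dt: float = 0.005
    duration: float = 0.800

    def __post_init__(self):
        for name in ("spatial_fwhm", "temporal_tau", "spacing", "dt", "duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_receptors < 2:
            raise ValueError("need at least 2 receptors")
        if self.duration < self.dt:
            raise ValueError("duration shorter than one time step")
        n = self.duration / self.dt
        if not np.isclose(n, round(n)):
            raise ValueError("duration must be an integer multiple of dt")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    def times(self) -> np.ndarray:
        return np.arange(self.n_steps) * self.dt

    def temporal_kernel(self) -> np.ndarray:
        """Causal exponential on the dt grid, unit discrete sum.

        Discretized by first-order hold: the weights are the exact
        convolution of exp(-t/tau)/tau with the linear interpolant of the
        sampled signal, so the filter's effective lag is exactly tau rather
        than being biased by the coarse (dt ~ tau/2) sampling.
        """
        n_k = int(np.ceil(25.0 * self.temporal_tau / self.dt)) + 1
        r = self.dt / self.temporal_tau
        a = np.exp(-r)
        w = np.empty(n_k)
        w[0] = 1.0 - (1.0 - a) / r
        w[1:] = a ** np.arange(1, n_k) * (np.exp(r) + a - 2.0) / r
        return w / w.sum()


@dataclass(frozen=True)
class MotionClip:
    """Responses of the receptor array to one translating panorama."""

    V: np.ndarray  # (n_receptors, n_steps)
    velocity: float  # deg/s, constant over the clip
    image_ref: int | str = 0
    offset: float = 0.0

    def mirrored(self) -> "MotionClip":
        """Exact mirror partner: receptor order reversed, velocity negated."""
        return replace(self, V=self.V[::-1].copy(), velocity=-self.velocity)


def _blur_panorama(image: Image1D, fwhm: float) -> np.ndarray:
    """Circular Gaussian blur of the panorama on its own pixel grid."""
    sigma_px = fwhm * _FWHM_TO_SIGMA / image.pixel_pitch
    return convolve1d(image.contrast, _gaussian_kernel(sigma_px), mode="wrap")


def _interp_periodic(values: np.ndarray, pitch: float, x: np.ndarray) -> np.ndarray:
    """Linear interpolation of a periodic panorama at angles x (degrees)."""
    n = values.size
    pos = np.mod(x, n * pitch) / pitch
    i0 = np.floor(pos).astype(np.intp)
    frac = pos - i0
    i0 = np.mod(i0, n)
    i1 = np.mod(i0 + 1, n)
    return values[i0] * (1.0 - frac) + values[i1] * frac


def _temporal_filter(u: np.ndarray, cfg: PhotoreceptorConfig) -> np.ndarray:
    """Causal convolution with the photoreceptor kernel, zero initial state."""
    kernel = cfg.temporal_kernel()
    n_t = u.shape[-1]
    out = fftconvolve(u, kernel.reshape((1,) * (u.ndim - 1) + (-1,)), axes=-1)
    return out[..., :n_t]


def photoreceptor_response(
    image: Image1D,
    velocity: float,
    offset: float,
    cfg: PhotoreceptorConfig = PhotoreceptorConfig(),
) -> MotionClip:
    """Simulate the receptor array viewing ``image`` translating at ``velocity``.

    Receptor *i* (1-based) sits at ``offset + (i - 1) * spacing``; the
    panorama wraps periodically in azimuth.
    """
    if not np.isfinite(velocity):
        raise ValueError("velocity must be finite")
    blurred = _blur_panorama(image, cfg.spatial_fwhm)
    t = cfg.times()
    rec = np.arange(cfg.n_receptors) * cfg.spacing
    # u_i(t) = B(x_i - v t): the blurred panorama swept past receptor i
    x = offset + rec[:, None] - velocity * t[None, :]
    u = _interp_periodic(blurred, image.pixel_pitch, x)
    return MotionClip(V=_temporal_filter(u, cfg), velocity=velocity, offset=offset)


def movie_response(
    movie: np.ndarray,
    cfg: PhotoreceptorConfig,
    positions: np.ndarray,
    pixel_pitch: float,
    frame_rate: float,
    boundary: str = "periodic",
) -> np.ndarray:
    """Photoreceptor responses to an arbitrary space-time contrast movie.

    The movie (``n_frames x n_pixels``) is held piecewise constant in space
    and time: each pixel is ``pixel_pitch`` degrees wide and each frame lasts
    ``1/frame_rate`` seconds.  The same Gaussian/exponential kernels as
    :func:`photoreceptor_response` are applied, with responses read out at
    the angular ``positions`` (degrees).

    Returns an array of shape ``(len(positions), n_steps)`` on the cfg.dt
    time grid spanning the movie duration.
    """
    movie = np.asarray(movie, dtype=float)
    if not np.all(np.isfinite(movie)):
        raise ValueError("movie contains non-finite values")
    if boundary not in {"periodic", "clamp"}:
        raise ValueError(f"unknown boundary rule: {boundary}")
    n_frames, n_px = movie.shape
    span = n_px * pixel_pitch
    positions = np.asarray(positions, dtype=float)
    if boundary == "clamp" and (np.any(positions < 0) or np.any(positions >= span)):
        raise ValueError("position outside the movie's angular span")

    # piecewise-constant spatial upsampling to a grid no coarser than 1 deg
    up = max(1, int(np.ceil(pixel_pitch / 1.0)))
    fine_pitch = pixel_pitch / up
    fine = np.repeat(movie, up, axis=1)
    sigma_px = cfg.spatial_fwhm * _FWHM_TO_SIGMA / fine_pitch
    mode = "wrap" if boundary == "periodic" else "nearest"
    blurred = convolve1d(fine, _gaussian_kernel(sigma_px), axis=1, mode=mode)

    duration = n_frames / frame_rate
    n_t = int(round(duration / cfg.dt))
    t = np.arange(n_t) * cfg.dt
    frame_idx = np.minimum((t * frame_rate).astype(np.intp), n_frames - 1)

    # sample the blurred frames at the receptor positions, then roll time
    n_fine = blurred.shape[1]
    pos = positions if boundary == "periodic" else np.clip(positions, 0, span - 1e-9)
    grid = np.mod(pos, span) / fine_pitch
    i0 = np.floor(grid).astype(np.intp)
    frac = grid - i0
    i0 = np.mod(i0, n_fine)
    i1 = np.mod(i0 + 1, n_fine)
    sampled = blurred[:, i0] * (1.0 - frac) + blurred[:, i1] * frac  # (frames, pos)
    u = sampled[frame_idx].T  # (pos, time)
    return _temporal_filter(u, cfg)


@dataclass
class Ensemble:
    """Mirror-symmetrized collection of motion clips, stored as dense arrays.

    Mirror partners occupy adjacent rows (2k, 2k+1); the partner's receptor
    array is the exact reversal of the original's, with negated velocity.
    """

    V: np.ndarray  # (n_clips, n_receptors, n_steps)
    velocities: np.ndarray  # (n_clips,)
    image_refs: np.ndarray  # (n_clips,)
    offsets: np.ndarray  # (n_clips,)
    cfg: PhotoreceptorConfig = field(default_factory=PhotoreceptorConfig)
    mirror_paired: bool = True
    velocity_sd: float = 90.0
    seed: int | None = None

    def __len__(self) -> int:
        return self.V.shape[0]

    def __getitem__(self, k: int) -> MotionClip:
        return MotionClip(
            V=self.V[k],
            velocity=float(self.velocities[k]),
            image_ref=int(self.image_refs[k]),
            offset=float(self.offsets[k]),
        )

    def pooled_values(self) -> np.ndarray:
        """All V_i(t) samples pooled across receptors, times, and clips."""
        return self.V.ravel()

    def with_values(self, V_new: np.ndarray) -> "Ensemble":
        """Same metadata, new response array (e.g. after a front-end transform)."""
        if V_new.shape != self.V.shape:
            raise ValueError("transformed array must keep the ensemble shape")
        return replace_ensemble(self, V=V_new)


def replace_ensemble(ens: Ensemble, **kw) -> Ensemble:
    from dataclasses import replace as _replace

    return _replace(ens, **kw)


def build_ensemble(
    images: list[Image1D],
    n_motions: int,
    seed: int,
    cfg: PhotoreceptorConfig = PhotoreceptorConfig(),
    velocity_sd: float = 90.0,
) -> Ensemble:
    """Simulate ``n_motions`` random translations plus their mirror partners.

    Each motion draws a panorama uniformly from ``images``, an offset
    uniform on [0, 360), and a velocity from N(0, velocity_sd^2).  The
    returned ensemble holds ``2 * n_motions`` clips with mirror partners
    interleaved.  Image choice, offset, and velocity use independent child
    streams of the master seed, so the ensemble is reproducible.
    """
    if not images:
        raise ValueError("empty image list")
    if n_motions < 1:
        raise ValueError("n_motions must be >= 1")
    rng_img, rng_off, rng_vel = (
        np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(3)
    )
    idx = rng_img.integers(0, len(images), size=n_motions)
    offsets = rng_off.uniform(0.0, 360.0, size=n_motions)
    vels = rng_vel.normal(0.0, velocity_sd, size=n_motions)

    t = cfg.times()
    rec = np.arange(cfg.n_receptors) * cfg.spacing
    blurred = {k: _blur_panorama(images[k], cfg.spatial_fwhm) for k in set(idx.tolist())}
    pitch = images[0].pixel_pitch

    V = np.empty((2 * n_motions, cfg.n_receptors, cfg.n_steps))
    for k in set(idx.tolist()):
        rows = np.flatnonzero(idx == k)
        x = (
            offsets[rows, None, None]
            + rec[None, :, None]
            - vels[rows, None, None] * t[None, None, :]
        )
        u = _interp_periodic(blurred[k], pitch, x)
        v_filt = _temporal_filter(u.reshape(-1, cfg.n_steps), cfg).reshape(u.shape)
        V[2 * rows] = v_filt
        V[2 * rows + 1] = v_filt[:, ::-1, :]  # exact mirror: receptors relabeled

    velocities = np.repeat(vels, 2)
    velocities[1::2] *= -1.0
    return Ensemble(
        V=V,
        velocities=velocities,
        image_refs=np.repeat(idx, 2),
        offsets=np.repeat(offsets, 2),
        cfg=cfg,
        mirror_paired=True,
        velocity_sd=velocity_sd,
        seed=seed,
    )


def save_ensemble(ens: Ensemble, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("V", data=ens.V, track_times=False)
        f.create_dataset("velocity", data=ens.velocities, track_times=False)
        f.create_dataset("image_ref", data=ens.image_refs, track_times=False)
        f.create_dataset("offset", data=ens.offsets, track_times=False)
        f.attrs["seed"] = -1 if ens.seed is None else ens.seed
        f.attrs["velocity_sd"] = ens.velocity_sd
        f.attrs["mirror_paired"] = ens.mirror_paired
        for name in ("spatial_fwhm", "temporal_tau", "spacing", "n_receptors", "dt", "duration"):
            f.attrs[name] = getattr(ens.cfg, name)


def load_ensemble(path) -> Ensemble:
    with h5py.File(path, "r") as f:
        cfg = PhotoreceptorConfig(
            spatial_fwhm=float(f.attrs["spatial_fwhm"]),
            temporal_tau=float(f.attrs["temporal_tau"]),
            spacing=float(f.attrs["spacing"]),
            n_receptors=int(f.attrs["n_receptors"]),
            dt=float(f.attrs["dt"]),
            duration=float(f.attrs["duration"]),
        )
        seed = int(f.attrs["seed"])
        return Ensemble(
            V=f["V"][...],
            velocities=f["velocity"][...],
            image_refs=f["image_ref"][...],
            offsets=f["offset"][...],
            cfg=cfg,
            mirror_paired=bool(f.attrs["mirror_paired"]),
            velocity_sd=float(f.attrs["velocity_sd"]),
            seed=None if seed < 0 else seed,
        )
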