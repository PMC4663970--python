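"""One-dimensional contrast panoramas: preprocessing and synthesis.

The motion-estimation pipeline consumes 360-degree, 1-degree-sampled rows
of contrast, the substrate that is rigidly translated past the modeled
photoreceptors.  Rows can be produced two ways:

* :func:`make_row_image` preprocesses a user-supplied grayscale image the
  way fly-eye simulations do: convert intensity to contrast, blur
  vertically with a Gaussian matching the photoreceptor acceptance angle,
  take the central row, tile it reflectively to span a full panorama, and
  block-average down to 1-degree pixels.

* :func:`synth_image` draws a synthetic panorama whose ensemble statistics
  emulate natural scenes: a heavy-tailed contrast distribution (tunable
  kurtosis), a light-dark asymmetry (positive skew), and spatial
  correlations that decay with distance.  The construction is a Gaussian
  1/f^slope random field passed through a monotone pointwise nonlinearity
  calibrated by moment matching.

All angles are degrees throughout the package; times are seconds.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import h5py
import numpy as np
from scipy.ndimage import convolve1d
from scipy.optimize import brentq

__all__ = [
    "Image1D",
    "SynthImageParams",
    "intensity_to_contrast",
    "make_row_image",
    "synth_image",
    "synth_image_ensemble",
    "read_grayscale",
    "save_images",
    "load_images",
]

#: full width at half maximum of the photoreceptor acceptance angle, degrees
DEFAULT_BLUR_FWHM = 5.7

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class Image1D:
    """A 360-degree contrast row sampled at ``pixel_pitch`` degrees."""

    contrast: np.ndarray
    pixel_pitch: float = 1.0
    source_tag: str = "natural"
    seed: int | None = None

    def __post_init__(self):
        c = np.asarray(self.contrast, dtype=float)
        object.__setattr__(self, "contrast", c)
        if not np.isclose(c.size * self.pixel_pitch, 360.0):
            raise ValueError(
                f"panorama must span 360 deg; got {c.size} px at {self.pixel_pitch} deg"
            )

    def __len__(self) -> int:
        return self.contrast.size


@dataclass(frozen=True)
class SynthImageParams:
    """Knobs of the synthetic panorama generator.

    ``spectral_slope`` is the exponent of the amplitude-spectrum power law
    (natural scenes are close to 1).  ``asymmetry`` injects positive skew
    through the pointwise output nonlinearity; 0 leaves the marginal
    symmetric.  ``target_kurtosis`` is the standardized fourth moment the
    pooled pixel marginal should attain (Gaussian = 3; natural contrast
    distributions are well above 3).
    """

    spectral_slope: float = 1.0
    asymmetry: float = 0.0
    target_kurtosis: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.target_kurtosis < 1.0:
            raise ValueError("kurtosis below 1 is unattainable by any distribution")


def intensity_to_contrast(intensity_image: np.ndarray) -> np.ndarray:
    """Convert a nonnegative intensity image to contrast (I - I0) / I0.

    I0 is the mean intensity over the whole image, so the output has zero
    mean by construction.  Images with I0 = 0 are rejected, not imputed.
    """
    img = np.asarray(intensity_image, dtype=float)
    if np.any(img < 0):
        raise ValueError("intensity image must be nonnegative")
    i0 = img.mean()
    if i0 <= 0.0:
        raise ValueError("mean intensity is zero; contrast undefined")
    return img / i0 - 1.0


def _gaussian_kernel(sigma_px: float) -> np.ndarray:
    """Discrete Gaussian truncated at +-3 sigma, renormalized to unit sum."""
    half = max(1, int(np.ceil(3.0 * sigma_px)))
    t = np.arange(-half, half + 1, dtype=float)
    k = np.exp(-0.5 * (t / sigma_px) ** 2)
    return k / k.sum()


def _reflect_tile(row: np.ndarray, n_out: int) -> np.ndarray:
    """Reflectively tile a row to ``n_out`` pixels, cropped about its center.

    The infinite extension alternates the row with its reversal (symmetric
    reflection about pixel edges, period 2L); the output window is centered
    on the base row so that mirroring the input mirrors the output.
    """
    n = row.size
    start = (n - n_out) // 2
    q = np.mod(np.arange(start, start + n_out), 2 * n)
    idx = np.where(q < n, q, 2 * n - 1 - q)
    return row[idx]


def make_row_image(
    contrast_image: np.ndarray,
    pixel_pitch: float,
    blur_fwhm: float = DEFAULT_BLUR_FWHM,
    out_pitch: float = 1.0,
) -> Image1D:
    """Reduce a 2-D contrast image to a 360-degree 1-degree-sampled row.

    Steps: column-wise Gaussian blur (FWHM ``blur_fwhm``), central-row
    extraction, reflective tiling out to 360 degrees, then block-averaging
    down to ``out_pitch`` pixels.

    Parameters
    ----------
    contrast_image
        2-D array of contrast values.
    pixel_pitch
        Angular spacing of the input pixels in degrees; must divide
        ``out_pitch`` evenly.
    """
    img = np.asarray(contrast_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D contrast image")
    if img.shape[1] * pixel_pitch < out_pitch:
        raise ValueError("image narrower than one output pixel")

    sigma_px = blur_fwhm * _FWHM_TO_SIGMA / pixel_pitch
    blurred = convolve1d(img, _gaussian_kernel(sigma_px), axis=0, mode="reflect")
    central = blurred[img.shape[0] // 2]

    factor = out_pitch / pixel_pitch
    if not np.isclose(factor, round(factor)):
        raise ValueError(
            f"input pitch {pixel_pitch} deg must divide output pitch {out_pitch} deg"
        )
    factor = int(round(factor))
    n_out_px = int(round(360.0 / pixel_pitch))
    tiled = _reflect_tile(central, n_out_px)
    row = tiled[: (n_out_px // factor) * factor].reshape(-1, factor).mean(axis=1)
    return Image1D(contrast=row, pixel_pitch=out_pitch, source_tag="natural")


# ---------------------------------------------------------------------------
# synthetic panoramas


def _gauss_hermite_moments(transform, n_nodes: int = 201):
    """Mean/variance/skew/kurtosis of transform(Z), Z ~ N(0,1), by quadrature."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    w = weights / weights.sum()
    y = transform(nodes)
    m = np.sum(w * y)
    yc = y - m
    var = np.sum(w * yc**2)
    skew = np.sum(w * yc**3) / var**1.5
    kurt = np.sum(w * yc**4) / var**2
    return m, var, skew, kurt


def _signed_power(z: np.ndarray, b: float) -> np.ndarray:
    return np.sign(z) * np.abs(z) ** b


def _make_transform(b: float, asymmetry: float):
    """Monotone pointwise map: signed power for tails, quadratic skew term."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(201)
    w = weights / weights.sum()
    m2 = np.sum(w * np.abs(nodes) ** (2.0 * b))

    def transform(z):
        s = _signed_power(z, b)
        return s + asymmetry * (s * s - m2)

    return transform


@lru_cache(maxsize=64)
def _calibrate_power(target_kurtosis: float, asymmetry: float) -> float:
    """Solve for the signed-power exponent hitting the target kurtosis."""

    def objective(b):
        _, _, _, kurt = _gauss_hermite_moments(_make_transform(b, asymmetry))
        return kurt - target_kurtosis

    lo, hi = 1e-3, 6.0
    flo, fhi = objective(lo), objective(hi)
    if flo * fhi > 0:
        raise ValueError(
            f"target kurtosis {target_kurtosis} out of the generator's reachable range"
        )
    return float(brentq(objective, lo, hi, xtol=1e-10))


def _power_law_field(n: int, slope: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean Gaussian field with amplitude spectrum ~ k^-slope, unit marginal SD."""
    n_half = n // 2
    k = np.arange(1, n_half + 1, dtype=float)
    amp = k**-slope
    coefs = np.zeros(n_half + 1, dtype=complex)
    coefs[1:n_half] = amp[: n_half - 1] * (
        rng.standard_normal(n_half - 1) + 1j * rng.standard_normal(n_half - 1)
    ) / np.sqrt(2.0)
    coefs[n_half] = amp[n_half - 1] * rng.standard_normal()  # Nyquist bin is real
    field = np.fft.irfft(coefs, n=n)
    # exact theoretical SD so the pooled marginal is standard normal
    var = (2.0 * np.sum(amp[: n_half - 1] ** 2) + amp[n_half - 1] ** 2) / n**2
    return field / np.sqrt(var)


def _synth_row(params: SynthImageParams, rng: np.random.Generator, n: int = 360) -> np.ndarray:
    b = _calibrate_power(params.target_kurtosis, params.asymmetry)
    transform = _make_transform(b, params.asymmetry)
    mean, _, _, _ = _gauss_hermite_moments(transform)
    z = _power_law_field(n, params.spectral_slope, rng)
    return transform(z) - mean


def synth_image(params: SynthImageParams) -> Image1D:
    """Draw one synthetic 360-degree panorama; deterministic for a fixed seed."""
    rng = np.random.default_rng(params.seed)
    return Image1D(
        contrast=_synth_row(params, rng),
        pixel_pitch=1.0,
        source_tag="synthetic",
        seed=params.seed,
    )


def synth_image_ensemble(params: SynthImageParams, n_images: int) -> list[Image1D]:
    """Draw an ensemble of panoramas from independent child streams of one seed."""
    seqs = np.random.SeedSequence(params.seed).spawn(n_images)
    out = []
    for i, seq in enumerate(seqs):
        rng = np.random.default_rng(seq)
        out.append(
            Image1D(
                contrast=_synth_row(params, rng),
                pixel_pitch=1.0,
                source_tag="synthetic",
                seed=params.seed,
            )
        )
    return out


# ---------------------------------------------------------------------------
# I/O


def read_grayscale(path: str | Path) -> np.ndarray:
    """Read a grayscale image from an NPY or PGM file as a float array."""
    path = Path(path)
    if path.suffix.lower() == ".npy":
        return np.asarray(np.load(path), dtype=float)
    if path.suffix.lower() == ".pgm":
        from PIL import Image as PILImage

        with PILImage.open(path) as im:
            return np.asarray(im, dtype=float)
    raise ValueError(f"unsupported image format: {path.suffix}")


def save_images(images: list[Image1D], path: str | Path) -> None:
    """Write an Image1D collection to HDF5 (``.h5``) or NPZ."""
    path = Path(path)
    arr = np.stack([im.contrast for im in images])
    pitch = images[0].pixel_pitch
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("images", data=arr, track_times=False)
            ds.attrs["pixel_pitch_deg"] = pitch
            f.attrs["pixel_pitch_deg"] = pitch
    elif path.suffix == ".npz":
        np.savez(path, images=arr, pixel_pitch_deg=pitch)
    else:
        raise ValueError(f"unsupported output format: {path.suffix}")


def load_images(path: str | Path) -> list[Image1D]:
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as f:
            arr = f["images"][...]
            pitch = float(f["images"].attrs["pixel_pitch_deg"])
    elif path.suffix == ".npz":
        with np.load(path) as f:
            arr = f["images"]
            pitch = float(f["pixel_pitch_deg"])
    else:
        raise ValueError(f"unsupported input format: {path.suffix}")
    return [Image1D(contrast=row, pixel_pitch=pitch) for row in arr]
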