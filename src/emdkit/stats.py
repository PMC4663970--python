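"""Moment statistics and spatial-covariance diagnostics.

Kurtosis here is the standardized fourth central moment mu4 / sigma^4
without the conventional "-3" excess shift, so a Gaussian scores 3, a
uniform distribution 1.8, and a symmetric two-point (Bernoulli +-1)
distribution 1 -- the minimum attainable by any distribution.  All moment
estimators use population (biased) normalization, appropriate for the
large-sample pooled signals they are applied to.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["kurtosis", "skewness", "moment_report", "MomentReport", "spatial_covariance"]


def kurtosis(samples: np.ndarray) -> float:
    """Standardized fourth central moment mu4/sigma^4 (no excess shift).

    Raises ``ValueError`` for fewer than 4 samples or zero variance.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 4:
        raise ValueError(f"need at least 4 samples, got {x.size}")
    x = x - x.mean()
    var = np.mean(x * x)
    if var <= 0.0:
        raise ValueError("kurtosis undefined for zero-variance samples")
    return float(np.mean(x**4) / var**2)


def skewness(samples: np.ndarray) -> float:
    """Standardized third central moment mu3/sigma^3 (population form)."""
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 3:
        raise ValueError(f"need at least 3 samples, got {x.size}")
    x = x - x.mean()
    var = np.mean(x * x)
    if var <= 0.0:
        raise ValueError("skewness undefined for zero-variance samples")
    return float(np.mean(x**3) / var**1.5)


@dataclass(frozen=True)
class MomentReport:
    """First four standardized moments of a pooled sample."""

    mean: float
    variance: float
    skewness: float
    kurtosis: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


def moment_report(samples: np.ndarray) -> MomentReport:
    x = np.asarray(samples, dtype=float).ravel()
    return MomentReport(
        mean=float(x.mean()),
        variance=float(x.var()),
        skewness=skewness(x),
        kurtosis=kurtosis(x),
        n=int(x.size),
    )


def spatial_covariance(images: np.ndarray, max_lag: float, pixel_pitch: float = 1.0) -> np.ndarray:
    """Ensemble- and position-averaged spatial autocovariance of panoramas.

    Parameters
    ----------
    images
        Array of shape ``(n_images, n_pixels)`` holding contrast rows that
        wrap periodically in azimuth.
    max_lag
        Largest separation, in degrees, to evaluate.  Must be below 180
        degrees: beyond the half-panorama the periodic wrap aliases lags.
    pixel_pitch
        Angular pixel spacing in degrees.

    Returns
    -------
    Covariance at lags ``0, pixel_pitch, 2*pixel_pitch, ... <= max_lag``;
    the lag-0 entry is the pooled variance.
    """
    imgs = np.atleast_2d(np.asarray(images, dtype=float))
    if imgs.shape[0] < 2:
        raise ValueError("need at least 2 images for an ensemble covariance")
    if max_lag >= 180.0:
        raise ValueError("max_lag must be < 180 deg (periodic aliasing)")
    n_lags = int(np.floor(max_lag / pixel_pitch)) + 1
    centered = imgs - imgs.mean()
    cov = np.empty(n_lags)
    for k in range(n_lags):
        cov[k] = np.mean(centered * np.roll(centered, -k, axis=1))
    return cov
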