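"""Microcanonical multifractal decomposition and feature extraction.

Stage 1 of the denoiser.  A non-negative density derived from the image
(by default the gradient magnitude) is aggregated at several small scales
``r`` by convolution with the slowly-decaying radial kernels

    Psi_gamma(x) = 1 / (1 + |x/r|^2)^gamma,   gamma in {1, 2, 3, 4},

truncated to a finite square support and *not* normalised, so that the
resulting measure mu(x, r) grows with r like a measure of a ball.  Under
the multifractal model the measure scales as a power law

    mu(x, r) ~ alpha(x) * r^d(x)       (r -> 0)

and the per-pixel singularity exponent d(x) is recovered by ordinary
least-squares regression of log mu against log r.  Pixels with the
smallest exponents form the most singular manifold (MSM), an edge-like
set that carries the sharpest, least noise-corrupted transitions of the
image; it is the feature set from which the reconstruction stage
re-estimates the image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .errors import DataError

__all__ = [
    "MeasureConfig",
    "ScaleStack",
    "ExponentMap",
    "FeatureMask",
    "wavelet_measure",
    "estimate_exponents",
    "level_set",
    "extract_msm",
]

#: Positivity floor applied to the measure before taking logarithms.
MEASURE_FLOOR = 1e-12


@dataclass(frozen=True)
class MeasureConfig:
    """Configuration of the multiscale measure.

    Parameters
    ----------
    scales : tuple of float
        Radii r in pixels, at least two, strictly increasing.  Small
        scales probe the r -> 0 regime of the power law.
    gammas : tuple of float
        Kernel decay exponents; the coefficient planes of all gammas are
        averaged per scale.
    density_mode : {"gradient_magnitude", "intensity"}
        Non-negative density whose multiscale aggregates are measured.
        ``gradient_magnitude`` (default) yields an edge-map-like MSM;
        ``intensity`` convolves the image values directly.
    kernel_truncation : float
        Half-width of the sampled kernel support as a multiple of r.
    """

    scales: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0)
    gammas: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0)
    density_mode: str = "gradient_magnitude"
    kernel_truncation: float = 3.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "scales", tuple(float(r) for r in self.scales))
        object.__setattr__(self, "gammas", tuple(float(g) for g in self.gammas))
        if len(self.scales) < 2:
            raise DataError("at least 2 scales are required for the log-log regression")
        if any(r <= 0 for r in self.scales):
            raise DataError("all scales must be > 0")
        if list(self.scales) != sorted(set(self.scales)):
            raise DataError("scales must be strictly increasing")
        if any(g < 1 for g in self.gammas) or not self.gammas:
            raise DataError("all kernel exponents gamma must be >= 1")
        if self.density_mode not in ("gradient_magnitude", "intensity"):
            raise DataError(f"unknown density_mode {self.density_mode!r}")
        if self.kernel_truncation <= 0:
            raise DataError("kernel_truncation must be > 0")


@dataclass
class ScaleStack:
    """Measure values mu(x, r) for every pixel over a set of scales.

    ``values`` has shape (n_scales, H, W) and is strictly positive
    (floored at :data:`MEASURE_FLOOR`) so logarithms are defined.
    """

    values: np.ndarray
    scales: np.ndarray


@dataclass
class ExponentMap:
    """Per-pixel singularity exponents with regression diagnostics.

    ``d`` is the log-log slope, ``log_alpha`` the intercept (log of the
    scale-independent prefactor) and ``r2`` the coefficient of
    determination of each pixel's fit.
    """

    d: np.ndarray
    log_alpha: np.ndarray
    r2: np.ndarray


@dataclass
class FeatureMask:
    """A binary pixel set together with the exponent cutoff that produced it."""

    mask: np.ndarray
    d_threshold: float


def _psi_kernel(r: float, gamma: float, truncation: float) -> np.ndarray:
    """Sample Psi((x)/r) on a square support of half-width ceil(truncation*r)."""
    h = int(math.ceil(truncation * r))
    yy, xx = np.mgrid[-h : h + 1, -h : h + 1].astype(np.float64)
    return 1.0 / (1.0 + (xx * xx + yy * yy) / (r * r)) ** gamma


def _density(b: np.ndarray, mode: str) -> np.ndarray:
    if mode == "intensity":
        return np.abs(b)
    gy, gx = np.gradient(b)
    return np.hypot(gx, gy)


def wavelet_measure(b: np.ndarray, cfg: MeasureConfig = MeasureConfig()) -> ScaleStack:
    """Compute the multiscale measure mu(x, r) of an image plane.

    For each scale the chosen density is convolved with the truncated,
    unnormalised kernel for every gamma; the coefficient planes are then
    averaged over gamma.  Boundaries are handled by mirror reflection and
    the result is floored at a tiny positive epsilon.
    """
    b = np.asarray(b, dtype=np.float64)
    if b.ndim != 2:
        raise DataError(f"expected a 2-D image plane, got ndim={b.ndim}")
    if not np.all(np.isfinite(b)):
        raise DataError("image contains non-finite values")
    h_max = int(math.ceil(cfg.kernel_truncation * max(cfg.scales)))
    if min(b.shape) < 2 * h_max + 1:
        raise DataError(
            f"image of shape {b.shape} is smaller than the largest kernel support "
            f"({2 * h_max + 1} pixels); reduce the scales or the truncation"
        )
    dens = _density(b, cfg.density_mode)
    planes = np.empty((len(cfg.scales),) + b.shape, dtype=np.float64)
    for i, r in enumerate(cfg.scales):
        hw = int(math.ceil(cfg.kernel_truncation * r))
        padded = np.pad(dens, hw, mode="symmetric")
        acc = np.zeros_like(b)
        for gamma in cfg.gammas:
            kern = _psi_kernel(r, gamma, cfg.kernel_truncation)
            conv = fftconvolve(padded, kern, mode="same")
            acc += conv[hw:-hw, hw:-hw]
        planes[i] = acc / len(cfg.gammas)
    np.maximum(planes, MEASURE_FLOOR, out=planes)
    return ScaleStack(values=planes, scales=np.asarray(cfg.scales, dtype=np.float64))


def estimate_exponents(stack: ScaleStack) -> ExponentMap:
    """Per-pixel OLS fit of log mu(x, r) against log r.

    The slope is the singularity exponent d(x), the intercept log alpha(x),
    and r2 the coefficient of determination.  Pixels whose measure is
    constant over r (zero total variance) fit the regression line exactly
    and get r2 = 1.
    """
    mu = np.asarray(stack.values, dtype=np.float64)
    if mu.ndim != 3 or mu.shape[0] < 2:
        raise DataError("stack must hold >= 2 scale planes")
    if np.any(mu <= 0):
        raise DataError("stack entries must be strictly positive (log domain)")
    lr = np.log(np.asarray(stack.scales, dtype=np.float64))
    lm = np.log(mu)
    lr_c = lr - lr.mean()
    lm_mean = lm.mean(axis=0)
    lm_c = lm - lm_mean
    sxx = float(np.sum(lr_c**2))
    slope = np.tensordot(lr_c, lm_c, axes=(0, 0)) / sxx
    intercept = lm_mean - slope * lr.mean()
    fitted_c = slope[None, :, :] * lr_c[:, None, None]
    ss_res = np.sum((lm_c - fitted_c) ** 2, axis=0)
    ss_tot = np.sum(lm_c**2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = 1.0 - ss_res / ss_tot
    r2 = np.where(ss_tot <= 1e-300, 1.0, r2)
    r2 = np.clip(r2, 0.0, 1.0)
    return ExponentMap(d=slope, log_alpha=intercept, r2=r2)


def level_set(em: ExponentMap, d_value: float, tol: float) -> FeatureMask:
    """Fractal component M_d: pixels with |d(x) - d_value| <= tol."""
    if tol < 0:
        raise DataError("tol must be >= 0")
    mask = np.abs(em.d - d_value) <= tol
    return FeatureMask(mask=mask, d_threshold=float(d_value))


def extract_msm(em: ExponentMap, quantile: float = 0.25) -> FeatureMask:
    """Extract the most singular manifold as a lower-quantile set of d(x).

    The literal argmin of d is generically a single pixel; the MSM of
    interest is the dense edge-like band of smallest exponents, so it is
    operationalised as all pixels at or below the given lower quantile of
    the exponent distribution.  Ties at the threshold are included, which
    makes the selection monotone in the quantile.
    """
    if not 0 < quantile <= 1:
        raise DataError(f"quantile must lie in (0, 1], got {quantile}")
    d = em.d
    thr = float(np.quantile(d, quantile))
    return FeatureMask(mask=d <= thr, d_threshold=thr)
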