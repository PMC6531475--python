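"""Image-quality metrics: MSE, PSNR and residual power spectral density.

PSNR uses the peak of the *reference* image, 20 log10(max(v)/sqrt(MSE)),
not the format's nominal maximum; the two conventions differ and the
reference-peak form is the one used throughout this package.

The residual PSD summarises where in frequency space a denoiser leaves
error: the squared magnitudes of the 2-D DFT of the residual v - v_hat
are radially averaged into log-spaced frequency bins (DC excluded), ready
for log-log plotting.  A better denoiser's curve lies lower, especially
at high frequencies where noise lives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError

__all__ = ["QualityReport", "PSDCurve", "mse", "psnr", "residual_psd", "evaluate_channels"]


@dataclass
class QualityReport:
    mse: float
    psnr_db: float
    channel: str = ""


@dataclass
class PSDCurve:
    """Radially averaged residual power spectrum.

    ``freq_bins`` are geometric bin centres in cycles/pixel; ``psd`` is
    the mean squared DFT magnitude of the residual over each annulus.
    """

    freq_bins: np.ndarray
    psd: np.ndarray


def _check_pair(v: np.ndarray, v_hat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    v = np.asarray(v, dtype=np.float64)
    v_hat = np.asarray(v_hat, dtype=np.float64)
    if v.shape != v_hat.shape:
        raise DataError(f"shape mismatch: {v.shape} vs {v_hat.shape}")
    return v, v_hat


def mse(v: np.ndarray, v_hat: np.ndarray) -> float:
    """Mean over all pixels of |v - v_hat|^2."""
    v, v_hat = _check_pair(v, v_hat)
    return float(np.mean((v - v_hat) ** 2))


def psnr(v: np.ndarray, v_hat: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB, peak taken from the reference v.

    Returns +inf when the images are identical (MSE = 0).
    """
    v, v_hat = _check_pair(v, v_hat)
    peak = float(np.max(v))
    if peak <= 0:
        raise DataError("reference image peak must be > 0 for PSNR")
    err = mse(v, v_hat)
    if err == 0:
        return float("inf")
    return 20.0 * np.log10(peak / np.sqrt(err))


def residual_psd(v: np.ndarray, v_hat: np.ndarray, n_bins: int = 32) -> PSDCurve:
    """Radially averaged power spectrum of the residual v - v_hat.

    Uses the unnormalised DFT convention (sum |F|^2 = N * sum(residual^2),
    Parseval).  Bin edges are log-spaced between the smallest positive
    radial frequency and the largest one present on the grid; the DC term
    is excluded so the mean offset does not dominate the curve.
    """
    v, v_hat = _check_pair(v, v_hat)
    if n_bins < 2:
        raise DataError("n_bins must be >= 2")
    delta = v - v_hat
    power = np.abs(np.fft.fft2(delta)) ** 2
    fy = np.fft.fftfreq(delta.shape[0])
    fx = np.fft.fftfreq(delta.shape[1])
    freq = np.hypot(fy[:, None], fx[None, :])
    nonzero = freq > 0
    fmin = float(freq[nonzero].min())
    fmax = float(freq.max())
    edges = np.geomspace(fmin, fmax, n_bins + 1)
    edges[0] *= 1 - 1e-12
    edges[-1] *= 1 + 1e-12
    which = np.digitize(freq[nonzero], edges) - 1
    which = np.clip(which, 0, n_bins - 1)
    psd = np.zeros(n_bins)
    counts = np.bincount(which, minlength=n_bins)
    sums = np.bincount(which, weights=power[nonzero], minlength=n_bins)
    filled = counts > 0
    psd[filled] = sums[filled] / counts[filled]
    centres = np.sqrt(edges[:-1] * edges[1:])
    return PSDCurve(freq_bins=centres, psd=psd)


def evaluate_channels(
    truth: np.ndarray, test: np.ndarray, channel_names: list[str] | None = None, n_bins: int = 32
) -> dict:
    """Per-channel MSE/PSNR plus the unweighted channel average.

    ``truth`` and ``test`` are (C, H, W) stacks.  Returns a plain dict
    suitable for JSON serialisation, including one PSD curve per channel.
    """
    truth = np.atleast_3d(np.asarray(truth, dtype=np.float64))
    test = np.atleast_3d(np.asarray(test, dtype=np.float64))
    if truth.ndim == 2:
        truth, test = truth[None], test[None]
    if truth.shape != test.shape:
        raise DataError(f"shape mismatch: {truth.shape} vs {test.shape}")
    names = channel_names or [f"channel_{i}" for i in range(truth.shape[0])]
    per_channel = []
    for c, name in enumerate(names):
        curve = residual_psd(truth[c], test[c], n_bins)
        per_channel.append(
            {
                "channel": name,
                "mse": mse(truth[c], test[c]),
                "psnr_db": psnr(truth[c], test[c]),
                "psd_freq": curve.freq_bins.tolist(),
                "psd": curve.psd.tolist(),
            }
        )
    return {
        "channels": per_channel,
        "mean_mse": float(np.mean([r["mse"] for r in per_channel])),
        "mean_psnr_db": float(np.mean([r["psnr_db"] for r in per_channel])),
    }
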