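"""Mixed Poisson-Gaussian noise model for fluorescence microscopy.

The observed image ``b`` is modelled per pixel as

    b = g0 * z + eps,    z ~ Poisson(v / g0),    eps ~ N(0, sigma^2)

where ``v`` is the clean intensity, ``g0`` the detector gain (scale of the
photon shot noise) and ``sigma`` the standard deviation of the additive
Gaussian measurement noise.  The model has closed-form moments

    E[b] = v        Var[b] = g0 * v + sigma^2

which the tests check by Monte Carlo.  The noisy output is deliberately
*not* clipped: the Gaussian term can drive pixels negative or above 1, and
downstream stages must accept that.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError

__all__ = ["NoiseParams", "add_mixed_pg_noise", "add_noise_multichannel", "noise_level_schedule"]


@dataclass(frozen=True)
class NoiseParams:
    """Parameters of the mixed Poisson-Gaussian model.

    Parameters
    ----------
    g0 : float
        Detector gain, > 0.  Smaller gain means more collected photons per
        intensity unit and therefore less relative shot noise.
    sigma : float
        Standard deviation of the additive Gaussian read-out noise, >= 0,
        in the same intensity units as the image.
    seed : int
        Seed for the pseudo-random draws.
    """

    g0: float
    sigma: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.g0 > 0:
            raise DataError(f"g0 must be > 0, got {self.g0}")
        if self.sigma < 0:
            raise DataError(f"sigma must be >= 0, got {self.sigma}")


def add_mixed_pg_noise(v: np.ndarray, params: NoiseParams) -> np.ndarray:
    """Corrupt a clean intensity plane with mixed Poisson-Gaussian noise.

    Parameters
    ----------
    v : ndarray
        Clean image plane, finite and non-negative.
    params : NoiseParams
        Gain, Gaussian sigma and seed.

    Returns
    -------
    ndarray
        ``g0 * Poisson(v / g0) + N(0, sigma^2)``, float64, same shape as
        ``v``.  Not clipped.
    """
    v = np.asarray(v, dtype=np.float64)
    if not np.all(np.isfinite(v)):
        raise DataError("clean image contains non-finite values")
    if np.any(v < 0):
        raise DataError("clean image must be non-negative")
    rng = np.random.default_rng(params.seed)
    z = rng.poisson(v / params.g0)
    b = params.g0 * z.astype(np.float64)
    if params.sigma > 0:
        b = b + rng.normal(0.0, params.sigma, size=v.shape)
    return b


def add_noise_multichannel(channels: np.ndarray, g0: float, sigma: float, seed: int = 0) -> np.ndarray:
    """Corrupt a (C, H, W) stack channel by channel with independent draws.

    A single user-facing seed is spawned into one independent sub-stream
    per channel, so channels are statistically independent but the whole
    corruption is reproducible from one integer.
    """
    channels = np.asarray(channels, dtype=np.float64)
    if channels.ndim != 3:
        raise DataError(f"expected (C, H, W) array, got ndim={channels.ndim}")
    child_seeds = np.random.SeedSequence(seed).spawn(channels.shape[0])
    out = np.empty_like(channels)
    for c, ss in enumerate(child_seeds):
        sub_seed = int(ss.generate_state(1)[0] % (2**31))
        out[c] = add_mixed_pg_noise(channels[c], NoiseParams(g0=g0, sigma=sigma, seed=sub_seed))
    return out


def noise_level_schedule(seed: int = 0) -> list[NoiseParams]:
    """The five benchmark noise levels, low to high.

    g0 = sigma in {1e-3, 1e-2.5, 1e-2, 1e-1.5, 1e-1}.
    """
    levels = [10.0**e for e in (-3.0, -2.5, -2.0, -1.5, -1.0)]
    return [NoiseParams(g0=g, sigma=g, seed=seed) for g in levels]
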