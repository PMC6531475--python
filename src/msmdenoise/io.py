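"""Image and configuration I/O.

Images are held internally as float64 in [0, 1] (noisy intermediates may
leave that range and are persisted as float32 TIFF, which is lossless at
working precision).  Integer formats are scaled by their nominal maximum
on read and clipped/quantised on write.
"""

from __future__ import annotations

import os

import numpy as np

from .errors import DataError
from .phantom import CHANNEL_NAMES, MultichannelImage

__all__ = ["read_image", "write_image"]

_NOMINAL_MAX = {np.dtype(np.uint8): 255.0, np.dtype(np.uint16): 65535.0}


def read_image(path: str | os.PathLike) -> MultichannelImage:
    """Read a TIFF or PNG image as a [0, 1]-scaled multichannel stack.

    Accepts 8/16-bit integer or 32/64-bit float data with 1 or 3
    channels (greyscale, RGB, or a 3-page/planar TIFF stack).  Integer
    values are divided by the format's nominal maximum; floats pass
    through unchanged.  Channel order is preserved.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise DataError(f"no such file: {path}")
    ext = os.path.splitext(path)[1].lower()
    try:
        if ext in (".tif", ".tiff"):
            import tifffile

            arr = tifffile.imread(path)
        elif ext == ".png":
            import imageio.v3 as iio

            arr = iio.imread(path)
        else:
            raise DataError(f"unsupported format {ext!r} for {path} (use TIFF or PNG)")
    except DataError:
        raise
    except Exception as exc:  # unreadable / truncated file
        raise DataError(f"could not read image {path}: {exc}") from exc

    arr = np.asarray(arr)
    if arr.dtype in _NOMINAL_MAX:
        data = arr.astype(np.float64) / _NOMINAL_MAX[arr.dtype]
    elif np.issubdtype(arr.dtype, np.floating):
        data = arr.astype(np.float64)
    else:
        raise DataError(f"unsupported bit depth {arr.dtype} in {path}")

    if data.ndim == 2:
        data = data[None]
    elif data.ndim == 3:
        # (H, W, C) interleaved -> (C, H, W) planar
        if data.shape[-1] in (1, 3) and data.shape[0] not in (1, 3):
            data = np.moveaxis(data, -1, 0)
        elif data.shape[0] not in (1, 3) and data.shape[-1] not in (1, 3):
            raise DataError(f"unsupported channel count in {path}: shape {arr.shape}")
        elif data.shape[0] not in (1, 3):
            data = np.moveaxis(data, -1, 0)
    else:
        raise DataError(f"unsupported dimensionality {arr.ndim} in {path}")
    names = CHANNEL_NAMES if data.shape[0] == 3 else ("intensity",)
    return MultichannelImage(channels=data, channel_names=names)


def write_image(img: MultichannelImage | np.ndarray, path: str | os.PathLike, bit_depth: int = 32) -> None:
    """Write a multichannel image as TIFF (or 8/16-bit PNG).

    ``bit_depth=32`` writes float32 TIFF and preserves values (including
    negatives) to float32 precision; 8 and 16 clip to [0, 1] and
    quantise.  Three-channel images are written interleaved RGB in the
    declared channel order.
    """
    if isinstance(img, MultichannelImage):
        data = img.channels
    else:
        data = np.asarray(img, dtype=np.float64)
        if data.ndim == 2:
            data = data[None]
    if not np.all(np.isfinite(data)):
        raise DataError("refusing to write non-finite pixel values")
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()

    if bit_depth == 32:
        out = data.astype(np.float32)
    elif bit_depth in (8, 16):
        scale = 255.0 if bit_depth == 8 else 65535.0
        dtype = np.uint8 if bit_depth == 8 else np.uint16
        out = np.round(np.clip(data, 0.0, 1.0) * scale).astype(dtype)
    else:
        raise DataError(f"unsupported bit depth {bit_depth} (use 8, 16 or 32)")

    if out.shape[0] == 3:
        out = np.moveaxis(out, 0, -1)  # interleaved RGB
    else:
        out = out[0]

    try:
        if ext in (".tif", ".tiff"):
            import tifffile

            photometric = "rgb" if out.ndim == 3 else "minisblack"
            tifffile.imwrite(path, out, photometric=photometric)
        elif ext == ".png":
            if bit_depth == 32:
                raise DataError("PNG does not support float32; use bit_depth 8 or 16")
            import imageio.v3 as iio

            iio.imwrite(path, out)
        else:
            raise DataError(f"unsupported format {ext!r} for {path} (use TIFF or PNG)")
    except DataError:
        raise
    except Exception as exc:
        raise DataError(f"could not write image {path}: {exc}") from exc
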