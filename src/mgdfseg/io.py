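"""Raster and configuration I/O.

Images live in memory as float 2-D arrays on the nominal 0-255 scale,
(row, col) indexed.  Binary masks are stored on disk as single-channel
PNGs with {0, 255} and mapped to {0, 1} in memory.  Vesselness maps
carry signed values in (-1, 1) and are persisted as 32-bit float TIFF
rasters.  Configurations are flat YAML key-value files mirroring
:class:`~mgdfseg.config.RunConfig`.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import imageio.v3 as iio
import numpy as np
import yaml

from .config import RunConfig

__all__ = [
    "load_image",
    "save_image",
    "load_mask",
    "save_mask",
    "load_float_map",
    "save_float_map",
    "load_config",
    "save_config",
]

PathLike = Union[str, Path]

_LUMA = np.array([0.299, 0.587, 0.114])


def load_image(path: PathLike, channel_policy: str = "green") -> np.ndarray:
    """Read a raster image as a float 2-D grid on the 0-255 scale.

    RGB(A) inputs are reduced per ``channel_policy``: ``green`` (the
    channel with the best vessel contrast in fundus photographs),
    ``luminance`` (ITU-R 601 weights) or ``as_is`` (grayscale inputs
    only).  8-bit data passes through; 16-bit data is rescaled by
    255/65535.  Per-image contrast is never renormalized.
    """
    if channel_policy not in ("green", "luminance", "as_is"):
        raise ValueError(f"unknown channel_policy {channel_policy!r}")
    path = Path(path)
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # corrupt/undecodable file
        raise OSError(f"cannot decode image file {path}: {exc}") from exc
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        if arr.shape[2] != 3:
            raise ValueError(
                f"unsupported channel count {arr.shape[2]} in {path}"
            )
        if channel_policy == "green":
            arr = arr[:, :, 1]
        elif channel_policy == "luminance":
            arr = arr.astype(float) @ _LUMA
        else:
            raise ValueError(
                f"channel_policy 'as_is' requires a grayscale image, {path} is multichannel"
            )
    elif arr.ndim != 2:
        raise ValueError(f"unsupported image dimensionality {arr.ndim} in {path}")
    if arr.dtype == np.uint16:
        out = arr.astype(float) * (255.0 / 65535.0)
    else:
        out = arr.astype(float)
    return out


def save_image(image: np.ndarray, path: PathLike) -> None:
    """Write a 0-255 image as 8-bit PNG (values clipped and rounded)."""
    arr = np.clip(np.asarray(image, float), 0, 255)
    iio.imwrite(Path(path), np.round(arr).astype(np.uint8))


def load_mask(path: PathLike) -> np.ndarray:
    """Read a mask PNG ({0, 255} on disk) into a {0, 1} uint8 grid."""
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    return (arr > 127).astype(np.uint8)


def save_mask(mask: np.ndarray, path: PathLike) -> None:
    """Write a {0, 1} mask as a single-channel {0, 255} PNG (lossless
    round trip with :func:`load_mask`)."""
    arr = np.asarray(mask)
    vals = np.unique(arr)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"mask must contain only 0/1 values, found {vals[:5]}")
    iio.imwrite(Path(path), (arr.astype(np.uint8) * 255))


def load_float_map(path: PathLike) -> np.ndarray:
    """Read a floating-point raster (vesselness map, phantom image)."""
    return np.asarray(iio.imread(Path(path)), dtype=np.float64)


def save_float_map(data: np.ndarray, path: PathLike) -> None:
    """Write a 32-bit float TIFF raster (preserves signed values)."""
    iio.imwrite(Path(path), np.asarray(data, dtype=np.float32))


def load_config(path: PathLike) -> RunConfig:
    """Read a flat YAML key-value file into a validated RunConfig."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must hold a flat key-value mapping")
    return RunConfig.from_dict(data)


def save_config(cfg: RunConfig, path: PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
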