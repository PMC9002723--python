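"""Image I/O, luminance/chrominance decomposition, and chroma fusion.

All images are held internally as float64 rasters on [0, 1] (top-left
origin, row-major).  Chroma planes stay on the 8-bit [0, 255] scale so the
weighted chroma fusion rule applies with its mid-intensity constant
tau = 128 literally.  The color matrix is ITU-R BT.601 full range (the
JPEG convention for 8-bit stills).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

TAU = 128.0

# BT.601 full-range RGB -> YCbCr.  Y on [0,1]; Cb/Cr offsets added on the
# 8-bit scale afterwards.
_FWD = np.array(
    [
        [0.299, 0.587, 0.114],
        [-0.168735892, -0.331264108, 0.5],
        [0.5, -0.418687589, -0.081312411],
    ]
)
_INV = np.linalg.inv(_FWD)


@dataclass
class RasterImage:
    """H×W (gray) or H×W×3 (RGB) raster on [0, 1] plus its file bit depth."""

    pixels: np.ndarray
    bit_depth: int = 8

    @property
    def is_color(self) -> bool:
        return self.pixels.ndim == 3

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim not in (2, 3):
            raise ValueError("raster must be H×W or H×W×3")
        if self.pixels.ndim == 3 and self.pixels.shape[2] != 3:
            raise ValueError("color rasters must have exactly 3 channels")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("degenerate raster")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("raster contains non-finite values")


@dataclass
class LumaChroma:
    """Luminance on [0,1]; Cb/Cr on the 8-bit [0,255] scale; tau = 128."""

    Y: np.ndarray
    Cb: np.ndarray
    Cr: np.ndarray
    tau: float = TAU


def read_image(path) -> RasterImage:
    """Read an 8- or 16-bit PNG/TIFF as a unit-interval raster."""
    path = Path(path)
    if not path.exists():
        raise OSError(f"no such image file: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend specific
        raise OSError(f"unreadable image file {path}: {exc}") from exc
    if arr.dtype == np.uint8:
        depth, scale = 8, 255.0
    elif arr.dtype == np.uint16:
        depth, scale = 16, 65535.0
    else:
        raise ValueError(f"unsupported sample type {arr.dtype} in {path}")
    if arr.ndim == 3 and arr.shape[2] not in (1, 3):
        raise ValueError(f"unsupported channel count {arr.shape[2]} in {path}")
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    return RasterImage(arr.astype(np.float64) / scale, bit_depth=depth)


def write_image(path, img: RasterImage) -> None:
    """Write a raster at its recorded bit depth (8 -> uint8, 16 -> uint16).

    16-bit color PNG is not supported by the PNG backend; use TIFF for
    16-bit RGB output.
    """
    path = Path(path)
    scale = 255.0 if img.bit_depth == 8 else 65535.0
    dtype = np.uint8 if img.bit_depth == 8 else np.uint16
    if img.bit_depth == 16 and img.is_color and path.suffix.lower() == ".png":
        raise ValueError("16-bit RGB PNG is unsupported; write TIFF instead")
    data = np.clip(np.rint(img.pixels * scale), 0, scale).astype(dtype)
    iio.imwrite(path, data)


def rgb_to_ycbcr(img: RasterImage) -> LumaChroma:
    """Decompose an RGB raster into Y on [0,1] and Cb/Cr on [0,255]."""
    if not img.is_color:
        raise ValueError("rgb_to_ycbcr expects a 3-channel raster")
    ycc = img.pixels @ _FWD.T
    return LumaChroma(Y=ycc[:, :, 0], Cb=ycc[:, :, 1] * 255.0 + TAU, Cr=ycc[:, :, 2] * 255.0 + TAU)


def ycbcr_to_rgb(lc: LumaChroma) -> RasterImage:
    """Exact matrix inverse of :func:`rgb_to_ycbcr` (then clipped to [0,1])."""
    ycc = np.stack(
        [lc.Y, (np.asarray(lc.Cb) - TAU) / 255.0, (np.asarray(lc.Cr) - TAU) / 255.0],
        axis=-1,
    )
    rgb = ycc @ _INV.T
    return RasterImage(np.clip(rgb, 0.0, 1.0))


def to_luma_chroma(img: RasterImage) -> LumaChroma:
    """Luma/chroma for any raster; grayscale maps to neutral chroma."""
    if img.is_color:
        return rgb_to_ycbcr(img)
    neutral = np.full_like(img.pixels, TAU)
    return LumaChroma(Y=img.pixels.copy(), Cb=neutral, Cr=neutral.copy())


def fuse_chroma(channels, tau: float = TAU, zero_tol: float = 1e-8) -> np.ndarray:
    """Fuse N chroma planes by signed distance-from-neutral weighting.

    Per pixel, Cf = sum_i Ci (Ci - tau) / sum_i (Ci - tau); where the
    denominator vanishes (within ``zero_tol``, guarding float noise) the
    fused chroma is the neutral value tau.  Output clipped to [0, 255].
    """
    planes = [np.asarray(c, dtype=np.float64) for c in channels]
    if not planes:
        raise ValueError("need at least one chroma plane")
    shape = planes[0].shape
    for p in planes:
        if p.shape != shape:
            raise ValueError("chroma planes must share a shape")
    # canonical per-pixel ordering makes the summation exactly
    # permutation-invariant (float addition is order-sensitive)
    stack = np.sort(np.stack(planes), axis=0)
    dev = stack - tau
    den = dev.sum(axis=0)
    num = (stack * dev).sum(axis=0)
    safe = np.abs(den) > zero_tol
    out = np.full(shape, tau, dtype=np.float64)
    np.divide(num, den, out=out, where=safe)
    return np.clip(out, 0.0, 255.0)
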