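"""Synthetic training data: multi-focus defocus sets and exposure stacks.

Large all-in-focus photo collections with per-pixel defocus ground truth do
not exist, so multi-focus training data is simulated: a clear image is
Gaussian-blurred (sigma drawn from [1, 2]); binary complementary masks
P_i partition the frame; the i-th defocused image takes the clear image on
its mask and the blurred image elsewhere:

    D_i(x, y) = I_clear(x, y) P_i(x, y) + I_blur(x, y) (1 - P_i(x, y)).

The masks come from two procedural families: *basal masks* (coarse
partitions of the frame into 1-4 parts) and *shape masks* (free-form
connected binary figures covering 15-60% of the frame), intersected and
then merged/split until the requested number of parts remains.  A
procedural textured-image generator stands in for photographic crops, and
a latent-radiance renderer produces bracketed exposure stacks with a
tone-mapped reference, so everything trains and tests without downloads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from math import ceil
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "MaskSet",
    "FocusSet",
    "ExposureSet",
    "make_basal_masks",
    "make_shape_mask",
    "compose_partition",
    "synthesize_focus_set",
    "make_synthetic_raw",
    "make_exposure_set",
    "write_focus_dataset",
    "SHAPE_LIBRARY_SIZE",
]

SHAPE_LIBRARY_SIZE = 213  # size of the procedural shape-mask library
MIN_REGION_FRACTION = 0.01


def _min_region_pixels(area: int) -> int:
    return max(1, ceil(MIN_REGION_FRACTION * area))


@dataclass
class MaskSet:
    """M binary planes forming an exact partition of the frame."""

    masks: np.ndarray  # (M, H, W), values {0, 1}

    def __post_init__(self):
        m = np.asarray(self.masks)
        if m.ndim != 3 or not (2 <= m.shape[0] <= 8):
            raise ValueError("a MaskSet holds 2-8 planes")
        if not np.isin(m, (0, 1)).all():
            raise ValueError("masks must be binary")
        if not (m.sum(axis=0) == 1).all():
            raise ValueError("masks must partition the frame exactly")
        area = m.shape[1] * m.shape[2]
        if (m.sum(axis=(1, 2)) < _min_region_pixels(area)).any():
            raise ValueError("every mask needs at least 1% of the pixels")
        self.masks = m.astype(np.uint8)

    @property
    def M(self) -> int:
        return self.masks.shape[0]


@dataclass
class FocusSet:
    """M defocused images, their partition masks, and the ground truth."""

    defocused: np.ndarray  # (M, H, W)
    clear: np.ndarray  # (H, W)
    blurred: np.ndarray  # (H, W)
    masks: MaskSet
    sigma: float


@dataclass
class ExposureSet:
    """K bracketed LDR renderings of one latent radiance map."""

    ldrs: np.ndarray  # (K, H, W) in [0, 1]
    reference: np.ndarray  # (H, W) tone-mapped radiance
    gains: np.ndarray  # (K,)
    radiance: np.ndarray  # (H, W) latent scene radiance


def make_basal_masks(size: tuple[int, int]) -> list[np.ndarray]:
    """The four coarse partitions of the frame: 1, 2, 3 and 4 parts.

    Geometry: whole frame; left/right halves; vertical thirds; quadrants.
    Every region is connected and each partition tiles the frame exactly.
    """
    h, w = size
    if h < 8 or w < 8:
        raise ValueError("basal masks need a frame of at least 8x8")
    partitions: list[np.ndarray] = [np.ones((1, h, w), dtype=np.uint8)]

    p2 = np.zeros((2, h, w), dtype=np.uint8)
    p2[0, :, : w // 2] = 1
    p2[1, :, w // 2 :] = 1
    partitions.append(p2)

    p3 = np.zeros((3, h, w), dtype=np.uint8)
    cuts = [0, w // 3, 2 * w // 3, w]
    for i in range(3):
        p3[i, :, cuts[i] : cuts[i + 1]] = 1
    partitions.append(p3)

    p4 = np.zeros((4, h, w), dtype=np.uint8)
    p4[0, : h // 2, : w // 2] = 1
    p4[1, : h // 2, w // 2 :] = 1
    p4[2, h // 2 :, : w // 2] = 1
    p4[3, h // 2 :, w // 2 :] = 1
    partitions.append(p4)
    return partitions


def _star_region(rng: np.random.Generator, size, target: float, harmonics: int) -> np.ndarray:
    """A star-convex region around a random center with a wavy radius profile."""
    h, w = size
    cy = rng.uniform(0.3 * h, 0.7 * h)
    cx = rng.uniform(0.3 * w, 0.7 * w)
    n_theta = 256
    theta = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    profile = np.ones(n_theta)
    for k in range(1, harmonics + 1):
        amp = rng.uniform(0.0, 0.35 / k)
        phase = rng.uniform(0, 2 * np.pi)
        profile += amp * np.cos(k * theta + phase)
    profile = np.maximum(profile, 0.2)
    # scale so that the enclosed area ~ target fraction of the frame
    base = np.sqrt(2 * target * h * w / (profile**2).sum() * n_theta / (2 * np.pi)) * np.sqrt(
        2 * np.pi / n_theta
    )
    yy, xx = np.mgrid[0:h, 0:w]
    ang = np.arctan2(yy - cy, xx - cx) % (2 * np.pi)
    rad = np.hypot(yy - cy, xx - cx)
    idx = (ang / (2 * np.pi) * n_theta).astype(int) % n_theta
    return (rad <= base * profile[idx]).astype(np.uint8)


def _blob_region(rng: np.random.Generator, size, target: float) -> np.ndarray:
    h, w = size
    noise = rng.normal(size=(h, w))
    smooth = ndimage.gaussian_filter(noise, sigma=max(2.0, min(h, w) / 12))
    thresh = np.quantile(smooth, 1.0 - target)
    mask = smooth > thresh
    labels, n = ndimage.label(mask)
    if n == 0:
        return np.zeros((h, w), dtype=np.uint8)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    return (labels == (1 + int(np.argmax(sizes)))).astype(np.uint8)


def make_shape_mask(size: tuple[int, int], seed: int) -> np.ndarray:
    """A connected binary figure covering 15-60% of the frame.

    Deterministic per seed.  Drawn from three families (ellipse-like,
    wavy polygon, smoothed-noise blob) to mimic a varied mask library.
    """
    h, w = size
    area = h * w
    for attempt in range(32):
        rng = np.random.default_rng([int(seed) % (2**31), attempt])
        target = rng.uniform(0.20, 0.55)
        family = rng.integers(3)
        if family == 0:
            mask = _star_region(rng, size, target, harmonics=1)  # ellipse-like
        elif family == 1:
            mask = _star_region(rng, size, target, harmonics=5)  # wavy polygon
        else:
            mask = _blob_region(rng, size, target)
        frac = mask.sum() / area
        if 0.15 <= frac <= 0.60:
            return mask
    raise RuntimeError("shape-mask generation failed to converge")  # pragma: no cover


def _split_piece(piece: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a region in two near-equal halves along its longer extent."""
    ys, xs = np.nonzero(piece)
    if ys.size < 2:
        raise ValueError("cannot split a region of fewer than 2 pixels")
    span_y = ys.max() - ys.min()
    span_x = xs.max() - xs.min()
    coord = ys if span_y >= span_x else xs
    cut = np.median(coord)
    sel = coord <= cut
    if sel.all() or not sel.any():  # all pixels on one side of the median
        order = np.argsort(coord, kind="stable")
        sel = np.zeros(coord.size, dtype=bool)
        sel[order[: coord.size // 2]] = True
    a = np.zeros_like(piece)
    b = np.zeros_like(piece)
    a[ys[sel], xs[sel]] = 1
    b[ys[~sel], xs[~sel]] = 1
    return a, b


def compose_partition(
    M: int, basal: np.ndarray, shape: np.ndarray, seed: int = 0
) -> MaskSet:
    """Intersect a basal partition with a shape mask, then merge/split
    deterministically until exactly M complementary masks remain."""
    if not 2 <= M <= 8:
        raise ValueError("M must lie in [2, 8]")
    if basal.shape[1:] != shape.shape:
        raise ValueError("basal and shape masks must share the frame size")
    shape = shape.astype(np.uint8)
    pieces = []
    for region in basal:
        for part in (region * shape, region * (1 - shape)):
            if part.any():
                pieces.append(part.astype(np.uint8))
    min_px = _min_region_pixels(shape.size)

    def sizes():
        return [int(p.sum()) for p in pieces]

    for _ in range(64):
        # merge the two smallest while too many pieces or any piece too small
        while len(pieces) > M or (len(pieces) > 1 and min(sizes()) < min_px):
            order = np.argsort(sizes(), kind="stable")
            i, j = sorted((order[0], order[1]))
            merged = pieces[i] | pieces[j]
            pieces = [p for k, p in enumerate(pieces) if k not in (i, j)]
            pieces.append(merged)
        if len(pieces) == M and min(sizes()) >= min_px:
            break
        # too few pieces: split the largest
        while len(pieces) < M:
            order = np.argsort(sizes(), kind="stable")
            big = pieces.pop(int(order[-1]))
            a, b = _split_piece(big)
            pieces += [a, b]
    return MaskSet(np.stack(pieces))


def synthesize_focus_set(
    clear: np.ndarray,
    M: int,
    sigma: float | None = None,
    seed: int = 0,
) -> FocusSet:
    """Build one multi-focus set from a clear image (defocus blending)."""
    clear = np.asarray(clear, dtype=np.float64)
    if clear.min() < 0 or clear.max() > 1:
        raise ValueError("clear image must lie in [0, 1]")
    rng = np.random.default_rng([int(seed) % (2**31), 11])
    if sigma is None:
        sigma = float(rng.uniform(1.0, 2.0))
    if not 1.0 <= sigma <= 2.0:
        raise ValueError("blur sigma must lie in [1, 2]")
    blurred = ndimage.gaussian_filter(
        clear, sigma=sigma, mode="reflect", radius=ceil(3 * sigma)
    )
    basal_choice = int(rng.integers(4))
    basal = make_basal_masks(clear.shape)[basal_choice]
    shape_seed = int(rng.integers(SHAPE_LIBRARY_SIZE))
    shape = make_shape_mask(clear.shape, seed=shape_seed)
    masks = compose_partition(M, basal, shape, seed=seed)
    P = masks.masks.astype(np.float64)
    defocused = clear[None] * P + blurred[None] * (1.0 - P)
    return FocusSet(
        defocused=defocused, clear=clear, blurred=blurred, masks=masks, sigma=sigma
    )


def make_synthetic_raw(seed: int, size: tuple[int, int] = (128, 128)) -> np.ndarray:
    """A deterministic broadband textured image on [0, 1].

    Mixes a directional gradient, a few geometric figures and band-passed
    noise so that Gaussian blur measurably removes energy.
    """
    h, w = size
    rng = np.random.default_rng([int(seed) % (2**31), 7])
    yy, xx = np.mgrid[0:h, 0:w] / max(h, w)
    ang = rng.uniform(0, 2 * np.pi)
    img = 0.4 * (np.cos(ang) * xx + np.sin(ang) * yy)
    for _ in range(rng.integers(3, 7)):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        ry, rx = rng.uniform(0.05, 0.3, size=2) * (h, w)
        level = rng.uniform(-0.5, 0.5)
        figure = ((np.mgrid[0:h][:, None] - cy) / ry) ** 2 + (
            (np.mgrid[0:w][None, :] - cx) / rx
        ) ** 2 <= 1.0
        img = img + level * figure
    noise = rng.normal(size=(h, w))
    band = ndimage.gaussian_filter(noise, 1.0) - ndimage.gaussian_filter(noise, 4.0)
    img = img + 0.6 * band
    lo, hi = img.min(), img.max()
    return (img - lo) / (hi - lo) if hi > lo else np.full((h, w), 0.5)


def make_exposure_set(
    seed: int, size: tuple[int, int] = (128, 128), K: int = 3
) -> ExposureSet:
    """Render K exposures of a latent radiance map, plus a tone-mapped
    reference.  Gains are geometric; clipping happens only at the bright
    end, so the union of unclipped pixels across exposures covers the
    frame."""
    if K < 2:
        raise ValueError("an exposure stack needs at least 2 frames")
    base = make_synthetic_raw(seed, size)
    radiance = 0.05 + 5.0 * base  # scene radiance, dynamic range ~100:1
    gains = np.geomspace(0.18, 1.6, K)
    ldrs = np.clip(gains[:, None, None] * radiance, 0.0, 1.0)
    tone = radiance / (1.0 + radiance)
    reference = tone / tone.max()
    return ExposureSet(ldrs=ldrs, reference=reference, gains=gains, radiance=radiance)


def write_focus_dataset(
    root,
    n_sets: int,
    min_m: int = 2,
    max_m: int = 8,
    size: int = 128,
    seed: int = 0,
) -> dict:
    """Write ``n_sets`` focus sets to disk (one directory per set) plus a
    JSON manifest; fully deterministic in the master seed."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    from . import color  # local import to avoid a cycle at module load

    manifest = {"master_seed": int(seed), "size": int(size), "sets": []}
    for i in range(n_sets):
        set_seed = (int(seed) * 100003 + i) % (2**31)
        rng = np.random.default_rng([set_seed, 3])
        M = int(rng.integers(min_m, max_m + 1))
        clear = make_synthetic_raw(set_seed, (size, size))
        fs = synthesize_focus_set(clear, M, seed=set_seed)
        d = root / f"set_{i:04d}"
        d.mkdir(exist_ok=True)
        color.write_image(d / "clear.png", color.RasterImage(fs.clear))
        for j in range(M):
            color.write_image(d / f"D_{j}.png", color.RasterImage(fs.defocused[j]))
            color.write_image(
                d / f"mask_{j}.png", color.RasterImage(fs.masks.masks[j].astype(float))
            )
        manifest["sets"].append({"id": i, "seed": set_seed, "M": M, "sigma": fs.sigma})
    (root / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
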