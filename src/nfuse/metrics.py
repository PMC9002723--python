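"""Evaluation metrics: image entropy, mutual information, MEF-SSIM.

All metrics operate on the luminance channel.  Entropy and mutual
information use 256-bin histograms on [0, 1] (8-bit convention); mutual
information is reported as the sum over sources of I(source_k; fused),
so two near-identical sources give MI close to twice the entropy.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .losses import MefSsimParams, mae_loss, mef_ssim

__all__ = ["entropy", "mutual_information", "evaluate_directory"]

_BINS = 256


def _hist_counts(img: np.ndarray, bins: int) -> np.ndarray:
    return np.histogram(img.ravel(), bins=bins, range=(0.0, 1.0))[0]


def entropy(image: np.ndarray, bins: int = _BINS) -> float:
    """Shannon entropy (bits) of the intensity histogram; empty bins
    contribute nothing."""
    counts = _hist_counts(np.asarray(image, dtype=np.float64), bins)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def mutual_information(
    sources: np.ndarray, fused: np.ndarray, bins: int = _BINS
) -> float:
    """Sum over sources of I(source_k; fused) from joint histograms."""
    sources = np.asarray(sources, dtype=np.float64)
    fused = np.asarray(fused, dtype=np.float64)
    if sources.ndim == 2:
        sources = sources[None]
    if sources.shape[1:] != fused.shape:
        raise ValueError("source/fused shapes differ")
    total = 0.0
    hf = entropy(fused, bins)
    for src in sources:
        joint = np.histogram2d(
            src.ravel(), fused.ravel(), bins=bins, range=[[0, 1], [0, 1]]
        )[0]
        pj = joint[joint > 0] / joint.sum()
        h_joint = float(-(pj * np.log2(pj)).sum())
        total += entropy(src, bins) + hf - h_joint
    return max(total, 0.0)


def _load_scene(scene_dir: Path):
    from . import color

    files = sorted(
        p for p in scene_dir.iterdir()
        if p.suffix.lower() in (".png", ".tif", ".tiff")
        and not p.stem.startswith("mask")
        and p.stem != "clear"
    )
    if not files:
        raise ValueError("no source images")
    rasters = [color.read_image(p) for p in files]
    lumas = [color.to_luma_chroma(r).Y for r in rasters]
    shape = lumas[0].shape
    if any(y.shape != shape for y in lumas):
        raise ValueError("source images in a scene must share a size")
    clear_path = scene_dir / "clear.png"
    reference = color.read_image(clear_path).pixels if clear_path.exists() else None
    return np.stack(lumas), reference


def evaluate_directory(
    root,
    fuse_fn,
    out_csv=None,
    mef_params: MefSsimParams | None = None,
) -> pd.DataFrame:
    """Fuse every scene directory under ``root`` and tabulate metrics.

    ``fuse_fn`` maps a (K, H, W) luminance stack to an (H, W) fused plane.
    Scenes that fail to load or fuse are reported in an ``error`` column
    rather than aborting the run.  Returns one row per scene; a ``mean``
    row summarizes the numeric columns.  If ``out_csv`` is given the table
    is also written as CSV.
    """
    root = Path(root)
    mef_params = mef_params or MefSsimParams()
    rows = []
    scene_dirs = sorted(d for d in root.iterdir() if d.is_dir()) if root.exists() else []
    for scene in scene_dirs:
        row: dict = {"scene": scene.name}
        try:
            sources, reference = _load_scene(scene)
            fused = np.asarray(fuse_fn(sources), dtype=np.float64)
            row["entropy"] = entropy(fused)
            row["mutual_information"] = mutual_information(sources, fused)
            row["mef_ssim"] = mef_ssim(sources, fused, mef_params)
            if reference is not None:
                row["mae"] = mae_loss(fused, reference)
        except Exception as exc:
            row["error"] = str(exc)
        rows.append(row)
    df = pd.DataFrame(rows)
    if not df.empty:
        numeric = df.select_dtypes("number")
        if not numeric.empty:
            mean_row = {"scene": "mean", **numeric.mean().to_dict()}
            df = pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    return df
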