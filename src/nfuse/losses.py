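"""Image-quality losses: mean absolute error, the MEF-SSIM no-reference
score and loss, and the task-level composite objectives.

MEF-SSIM evaluates a fused image against the *set* of source images
without a ground truth.  Each sliding window of each source is decomposed
into mean intensity, contrast (the Euclidean norm of the mean-removed
patch) and unit-norm structure.  The desired patch for the window takes
the highest contrast among the sources and a structure direction obtained
by averaging the sources' structures with weights that grow with their
contrast (power ``structure_weight_exponent``).  The per-window score is
the structure-only similarity between the desired patch and the
mean-removed fused patch; the final score is the mean over windows, and
the loss is one minus the score.  The score is differentiable in the
fused image (sources enter only through the constant desired patches).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ._autodiff import Tensor, window_dot, windowed_sum

__all__ = [
    "LossWeights",
    "MefSsimParams",
    "mae_loss",
    "mef_ssim",
    "mef_ssim_loss",
    "total_loss",
]


@dataclass
class LossWeights:
    """Composite-loss coefficients for one fusion task.

    Supervised tasks (a reference image exists) combine
    lambda1·MAE + lambda2·(1 − MEF-SSIM) + lambda3·L_ewc;
    unsupervised tasks use lambda1·(1 − MEF-SSIM) + lambda2·L_ewc.
    """

    lambda1: float
    lambda2: float
    lambda3: float = 0.0
    supervised: bool = True

    def __post_init__(self):
        if min(self.lambda1, self.lambda2, self.lambda3) < 0:
            raise ValueError("loss weights must be non-negative")

    @classmethod
    def for_supervised(cls, ewc_weight: float = 2e4) -> "LossWeights":
        return cls(lambda1=0.5, lambda2=0.5, lambda3=ewc_weight, supervised=True)

    @classmethod
    def for_unsupervised(cls, ewc_weight: float = 2e4) -> "LossWeights":
        return cls(lambda1=1.0, lambda2=ewc_weight, lambda3=0.0, supervised=False)

    @property
    def ewc_weight(self) -> float:
        return self.lambda3 if self.supervised else self.lambda2


@dataclass
class MefSsimParams:
    """Window geometry and stability constants of the MEF-SSIM kernel."""

    window: int = 8
    stride: int = 1
    dynamic_range: float = 1.0
    c_factor: float = 0.03  # C = (c_factor * dynamic_range)^2
    structure_weight_exponent: float = 4.0
    zero_contrast_epsilon: float = 1e-12

    def __post_init__(self):
        if self.window < 2 or self.stride < 1:
            raise ValueError("window must be >= 2 and stride >= 1")

    @property
    def C(self) -> float:
        return (self.c_factor * self.dynamic_range) ** 2


def mae_loss(fused, reference):
    """Mean absolute error over all pixels/channels (Tensor-aware)."""
    f = fused if isinstance(fused, Tensor) else Tensor(fused)
    r = reference if isinstance(reference, Tensor) else Tensor(reference)
    if f.shape != r.shape:
        raise ValueError(f"shape mismatch: {f.shape} vs {r.shape}")
    out = (f - r).abs().mean()
    return out if isinstance(fused, Tensor) else out.item()


def desired_patches(sources: np.ndarray, params: MefSsimParams) -> np.ndarray:
    """The (nH, nW, w, w) grid of zero-mean desired patches x-hat.

    Built from the sources only: contrast = max over sources of the
    mean-removed patch norm; structure = contrast-power-weighted average
    of unit structures, renormalized.  Windows where every source is
    constant (contrast below epsilon) yield a zero patch.
    """
    w, s = params.window, params.stride
    eps = params.zero_contrast_epsilon
    K = sources.shape[0]
    views = [
        sliding_window_view(src, (w, w))[::s, ::s] for src in sources
    ]  # K × (nH, nW, w, w)
    tilde = []
    contrast = []
    for v in views:
        mu = v.mean(axis=(2, 3), keepdims=True)
        xt = v - mu
        tilde.append(xt)
        contrast.append(np.sqrt((xt * xt).sum(axis=(2, 3))))
    contrast = np.stack(contrast)  # (K, nH, nW)
    chat = contrast.max(axis=0)
    weights = contrast ** params.structure_weight_exponent
    wsum = weights.sum(axis=0)
    sbar = np.zeros_like(tilde[0])
    for k in range(K):
        frac = np.divide(
            weights[k], wsum, out=np.zeros_like(wsum), where=wsum > eps
        )
        unit = tilde[k] / (contrast[k][:, :, None, None] + eps)
        sbar += frac[:, :, None, None] * unit
    snorm = np.sqrt((sbar * sbar).sum(axis=(2, 3)))
    shat = sbar / (snorm[:, :, None, None] + eps)
    xhat = chat[:, :, None, None] * shat
    xhat[chat <= eps] = 0.0
    return xhat


def mef_ssim(sources: np.ndarray, fused, params: MefSsimParams | None = None):
    """No-reference structural score of ``fused`` against the source set.

    Returns a float for an array input, or a differentiable scalar Tensor
    when ``fused`` is a Tensor.  Symmetric in the order of the sources.
    """
    params = params or MefSsimParams()
    sources = np.asarray(sources, dtype=np.float64)
    if sources.ndim != 3 or sources.shape[0] < 1:
        raise ValueError("sources must be a (K, H, W) stack with K >= 1")
    is_tensor = isinstance(fused, Tensor)
    f = fused if is_tensor else Tensor(fused)
    if f.shape != sources.shape[1:]:
        raise ValueError(f"fused shape {f.shape} != source shape {sources.shape[1:]}")
    w, s = params.window, params.stride
    if min(f.shape) < w:
        raise ValueError("image smaller than the MEF-SSIM window")
    n = w * w
    xhat = desired_patches(sources, params)
    var_x = (xhat * xhat).sum(axis=(2, 3))  # window-sum of xhat^2 = chat^2
    cross = window_dot(f, xhat, stride=s)  # sum of xhat * y per window
    s1 = windowed_sum(f, w, stride=s)
    s2 = windowed_sum(f * f, w, stride=s)
    var_y = s2 - s1 * s1 * (1.0 / n)  # window-sum of (y - mean)^2
    nC = n * params.C
    score = ((cross * 2.0 + nC) / (var_y + Tensor(var_x + nC))).mean()
    return score if is_tensor else score.item()


def mef_ssim_loss(sources, fused, params: MefSsimParams | None = None):
    """1 − MEF-SSIM, in [0, 2]; differentiable in the fused image."""
    score = mef_ssim(sources, fused, params)
    return 1.0 - score if isinstance(score, Tensor) else 1.0 - score


def total_loss(
    fused,
    sources,
    reference=None,
    ewc_penalty=0.0,
    weights: LossWeights | None = None,
    mef_params: MefSsimParams | None = None,
):
    """Task composite loss.

    Supervised: lambda1·MAE + lambda2·(1 − MEF-SSIM) + lambda3·L_ewc.
    Unsupervised: lambda1·(1 − MEF-SSIM) + lambda2·L_ewc.
    """
    weights = weights or LossWeights.for_supervised()
    nref = mef_ssim_loss(sources, fused, mef_params)
    if weights.supervised:
        if reference is None:
            raise ValueError("supervised loss requires a reference image")
        return (
            weights.lambda1 * mae_loss(fused, reference)
            + weights.lambda2 * nref
            + weights.lambda3 * ewc_penalty
        )
    return weights.lambda1 * nref + weights.lambda2 * ewc_penalty
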