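"""Toy-scale study harness: retention and pooling-ablation experiments.

These reproduce, at desk scale, the two directional findings the full
training pipeline is built around: (1) consolidating the first task with
EWC reduces how much its quality degrades while a second task trains, and
(2) max aggregation across input streams fuses better than sum
aggregation.  The scale — an 8-channel network, 32×32 images, 16 training
and 8 held-out sets per task, 300 iterations per task — is chosen so each
experiment completes in minutes on one CPU while the training signal is
still clearly above noise.  The toy runs use a learning rate of 1e-3:
at a few hundred iterations the full-scale rate of 1e-4 leaves the model
near its random initialization, which would make any comparison between
training regimes meaningless; the full-scale schedule constants remain
the defaults of :class:`~nfuse.trainer.TrainConfig`.
"""

from __future__ import annotations

from .ewc import EWCState
from .focus_synth import make_exposure_set, make_synthetic_raw, synthesize_focus_set
from .losses import MefSsimParams
from .network import FusionNet, NetConfig
from .trainer import (
    TaskSpec,
    TrainConfig,
    consolidate_task,
    evaluate_mef_ssim,
    train_task,
)

__all__ = [
    "make_exposure_task",
    "make_focus_task",
    "retention_experiment",
    "pooling_experiment",
]

TOY_SIZE = 32
TOY_CHANNELS = 8
TOY_ITERATIONS = 300
TOY_TRAIN_SETS = 16
TOY_EVAL_SETS = 8
TOY_LR = 1e-3


def _exposure_samples(seed: int, n: int, size: int, k: int) -> list[dict]:
    out = []
    for i in range(n):
        es = make_exposure_set((seed * 7919 + i) % (2**31), (size, size), K=k)
        out.append({"sources": es.ldrs, "reference": es.reference})
    return out


def _focus_samples(seed: int, n: int, size: int) -> list[dict]:
    out = []
    for i in range(n):
        s = (seed * 104729 + i) % (2**31)
        clear = make_synthetic_raw(s, (size, size))
        fs = synthesize_focus_set(clear, M=2 + (i % 2), seed=s)
        out.append({"sources": fs.defocused, "reference": fs.clear})
    return out


def make_exposure_task(
    seed: int,
    n_train: int = TOY_TRAIN_SETS,
    n_eval: int = TOY_EVAL_SETS,
    size: int = TOY_SIZE,
    k: int = 3,
) -> TaskSpec:
    """A supervised multi-exposure toy task with a held-out split."""
    return TaskSpec(
        name="multi_exposure",
        data=_exposure_samples(seed, n_train, size, k),
        eval_data=_exposure_samples(seed + 500009, n_eval, size, k),
        supervised=True,
        importance_subset_size=n_train,
    )


def make_focus_task(
    seed: int,
    n_train: int = TOY_TRAIN_SETS,
    n_eval: int = TOY_EVAL_SETS,
    size: int = TOY_SIZE,
) -> TaskSpec:
    """A supervised multi-focus toy task with a held-out split."""
    return TaskSpec(
        name="multi_focus",
        data=_focus_samples(seed, n_train, size),
        eval_data=_focus_samples(seed + 500009, n_eval, size),
        supervised=True,
        importance_subset_size=n_train,
    )


def _clone(model: FusionNet) -> FusionNet:
    twin = FusionNet(model.config)
    twin.load_state_arrays(model.state_arrays())
    return twin


def retention_experiment(
    seed: int,
    iterations: int = TOY_ITERATIONS,
    base_channels: int = TOY_CHANNELS,
) -> dict:
    """Train exposure then focus, with and without EWC, from one shared
    first-task model; report the first task's quality drop in each arm.

    Returns a dict with the exposure MEF-SSIM after task 1 and after task
    2 for both arms, and the corresponding drops (positive = forgetting).
    """
    mef = MefSsimParams()
    cfg = TrainConfig(master_seed=seed, patch=TOY_SIZE, initial_lr=TOY_LR)
    exposure = make_exposure_task(seed)
    focus = make_focus_task(seed + 1)

    model = FusionNet(NetConfig(base_channels=base_channels), seed=seed)
    train_task(model, exposure, EWCState(), cfg, iterations=iterations, mef_params=mef)
    state = consolidate_task(model, exposure, EWCState(), cfg, mef)
    score_t1 = evaluate_mef_ssim(model, exposure.eval_data, mef)

    with_ewc = _clone(model)
    train_task(with_ewc, focus, state, cfg, iterations=iterations, mef_params=mef)

    without_ewc = _clone(model)
    train_task(without_ewc, focus, EWCState(), cfg, iterations=iterations, mef_params=mef)

    s_with = evaluate_mef_ssim(with_ewc, exposure.eval_data, mef)
    s_without = evaluate_mef_ssim(without_ewc, exposure.eval_data, mef)
    return {
        "seed": seed,
        "iterations": iterations,
        "exposure_after_task1": score_t1,
        "exposure_after_task2_with_ewc": s_with,
        "exposure_after_task2_without_ewc": s_without,
        "drop_with_ewc": score_t1 - s_with,
        "drop_without_ewc": score_t1 - s_without,
        "focus_with_ewc": evaluate_mef_ssim(with_ewc, focus.eval_data, mef),
        "focus_without_ewc": evaluate_mef_ssim(without_ewc, focus.eval_data, mef),
    }


def pooling_experiment(
    seed: int,
    iterations: int = TOY_ITERATIONS,
    base_channels: int = TOY_CHANNELS,
    task: str = "multi_exposure",
) -> dict:
    """Train identical models with max vs sum stream aggregation on one toy
    task; report held-out MEF-SSIM for both aggregators.

    The contrast between the two tasks is instructive: focus sets have
    complementary content (each source is sharp somewhere else), which
    rewards selective max pooling; the synthetic exposure stacks are scalar
    multiples of one radiance map wherever unclipped, so additive pooling
    loses nothing there.
    """
    mef = MefSsimParams()
    cfg = TrainConfig(master_seed=seed, patch=TOY_SIZE, initial_lr=TOY_LR)
    spec = make_exposure_task(seed) if task == "multi_exposure" else make_focus_task(seed)
    scores = {}
    for agg in ("max", "sum"):
        model = FusionNet(
            NetConfig(base_channels=base_channels, aggregator=agg), seed=seed
        )
        train_task(model, spec, EWCState(), cfg, iterations=iterations,
                   mef_params=mef)
        scores[agg] = evaluate_mef_ssim(model, spec.eval_data, mef)
    return {"seed": seed, "iterations": iterations, "task": task, **scores}
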