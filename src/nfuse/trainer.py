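"""Sequential-task training with elastic weight consolidation.

Tasks are trained one after another.  While a task trains, the loss is its
own image-quality composite plus the task's EWC weight times the anchored
quadratic penalty built from all previously finished tasks (zero for the
first task).  When a task finishes, a small subset of its data is used to
estimate the Fisher-diagonal importance of every parameter under that
task's own loss, and the importance is added into the running EWC state
with the just-trained parameters as the new anchor.

Optimization is Adam (beta1 = 0.9, beta2 = 0.99), batch size 1, with the
learning rate starting at 1e-4 and halving every 5e4 iterations.  Every
random choice (sample order, crop position) is derived from the master
seed and the iteration index alone, so runs are reproducible and a run
resumed from a checkpoint retraces the uninterrupted trajectory exactly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor
from .ewc import EWCState, accumulate, estimate_importance, ewc_penalty
from .losses import LossWeights, MefSsimParams, mef_ssim, total_loss
from .network import FusionNet

__all__ = [
    "TaskSpec",
    "TrainConfig",
    "OptState",
    "lr_schedule",
    "train_task",
    "run_curriculum",
    "evaluate_mef_ssim",
]

TASK_NAMES = ("medical", "infrared_visible", "multi_exposure", "multi_focus")


@dataclass
class TaskSpec:
    """One fusion task: its data, supervision flag and loss weights.

    ``data`` is a list of samples, each a dict with key ``sources``
    ((K, H, W) float array) and, for supervised tasks, ``reference``
    ((H, W) float array).  ``eval_data`` is an optional held-out list in
    the same format.
    """

    name: str
    data: list
    supervised: bool
    weights: LossWeights | None = None
    epochs: int = 1
    eval_data: list = field(default_factory=list)
    importance_subset_size: int = 50

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.weights is None:
            self.weights = (
                LossWeights.for_supervised()
                if self.supervised
                else LossWeights.for_unsupervised()
            )
        if self.supervised:
            for s in self.data:
                if s.get("reference") is None:
                    raise ValueError(
                        f"supervised task {self.name!r} has a sample without a reference"
                    )

    @property
    def seed_tag(self) -> int:
        return zlib.crc32(self.name.encode()) % 65536


@dataclass
class TrainConfig:
    """Optimizer and schedule constants."""

    beta1: float = 0.9
    beta2: float = 0.99
    initial_lr: float = 1e-4
    lr_half_period: int = 50_000
    batch_size: int = 1
    patch: int = 128
    master_seed: int = 0
    adam_eps: float = 1e-8
    ewc_weight_warn_range: tuple[float, float] = (1e4, 3e4)
    eval_every: int = 100  # held-out MEF-SSIM cadence (0 disables)


@dataclass
class OptState:
    """Adam moments plus the global iteration counter (for the schedule)."""

    m: dict = field(default_factory=dict)
    v: dict = field(default_factory=dict)
    t: int = 0
    global_iter: int = 0

    def arrays(self) -> dict[str, np.ndarray]:
        out = {f"adam_m/{k}": v for k, v in self.m.items()}
        out.update({f"adam_v/{k}": v for k, v in self.v.items()})
        out["adam_t"] = np.array(self.t)
        out["global_iter"] = np.array(self.global_iter)
        return out

    @classmethod
    def from_arrays(cls, arrays: dict[str, np.ndarray]) -> "OptState":
        return cls(
            m={k.removeprefix("adam_m/"): np.array(v)
               for k, v in arrays.items() if k.startswith("adam_m/")},
            v={k.removeprefix("adam_v/"): np.array(v)
               for k, v in arrays.items() if k.startswith("adam_v/")},
            t=int(arrays["adam_t"]),
            global_iter=int(arrays["global_iter"]),
        )


def lr_schedule(iteration: int, config: TrainConfig) -> float:
    """initial_lr halved once per ``lr_half_period`` iterations."""
    if iteration < 0:
        raise ValueError("iteration must be >= 0")
    return config.initial_lr * 0.5 ** (iteration // config.lr_half_period)


def _adam_step(model: FusionNet, opt: OptState, lr: float, config: TrainConfig) -> None:
    opt.t += 1
    b1, b2, eps = config.beta1, config.beta2, config.adam_eps
    bias1 = 1.0 - b1**opt.t
    bias2 = 1.0 - b2**opt.t
    for k, p in model.params.items():
        g = p.grad
        if g is None:
            continue
        if k not in opt.m:
            opt.m[k] = np.zeros_like(p.data)
            opt.v[k] = np.zeros_like(p.data)
        opt.m[k] = b1 * opt.m[k] + (1 - b1) * g
        opt.v[k] = b2 * opt.v[k] + (1 - b2) * g * g
        p.data -= lr * (opt.m[k] / bias1) / (np.sqrt(opt.v[k] / bias2) + eps)


def _crop(arr: np.ndarray, top: int, left: int, patch: int) -> np.ndarray:
    return arr[..., top : top + patch, left : left + patch]


def _sample_for_iteration(task: TaskSpec, config: TrainConfig, iteration: int):
    """Deterministic sample + crop for one iteration (resume-safe)."""
    rng = np.random.default_rng(
        [config.master_seed % (2**31), task.seed_tag, iteration]
    )
    sample = task.data[int(rng.integers(len(task.data)))]
    sources = np.asarray(sample["sources"], dtype=np.float64)
    reference = sample.get("reference")
    h, w = sources.shape[1:]
    p = config.patch
    if h > p or w > p:
        top = int(rng.integers(h - p + 1)) if h > p else 0
        left = int(rng.integers(w - p + 1)) if w > p else 0
        sources = _crop(sources, top, left, p)
        if reference is not None:
            reference = _crop(np.asarray(reference, dtype=np.float64), top, left, p)
    return sources, reference


def train_task(
    model: FusionNet,
    task: TaskSpec,
    ewc_state: EWCState,
    config: TrainConfig,
    opt_state: OptState | None = None,
    start_iteration: int = 0,
    iterations: int | None = None,
    mef_params: MefSsimParams | None = None,
) -> tuple[list[dict], OptState]:
    """Optimize the task composite loss; returns (loss trace, opt state).

    The EWC anchor and importance are read-only here; gradient steps touch
    only the live parameters.
    """
    opt = opt_state or OptState()
    if iterations is None:
        iterations = task.epochs * len(task.data)
    mef_params = mef_params or MefSsimParams()
    lam = task.weights.ewc_weight
    if lam > 0 and not (
        config.ewc_weight_warn_range[0] <= lam <= config.ewc_weight_warn_range[1]
    ):
        import warnings

        warnings.warn(
            f"EWC weight {lam:g} outside the insensitive range "
            f"{config.ewc_weight_warn_range}; results may degrade",
            stacklevel=2,
        )
    trace: list[dict] = []
    use_penalty = lam > 0 and not ewc_state.empty
    # Under an active consolidation the normalization running statistics are
    # part of what must be preserved — the quadratic penalty cannot anchor
    # them — so later tasks train with frozen statistics (eval-mode
    # normalization), the usual frozen-BN fine-tuning regime.
    bn_training = not use_penalty
    for it in range(start_iteration, iterations):
        sources, reference = _sample_for_iteration(task, config, it)
        model.zero_grad()
        fused = model.forward(sources, training=bn_training, clip=False)
        penalty = ewc_penalty(model.params, ewc_state) if use_penalty else Tensor(0.0)
        loss = total_loss(
            fused,
            sources,
            reference=reference,
            ewc_penalty=penalty,
            weights=task.weights,
            mef_params=mef_params,
        )
        loss.backward()
        lr = lr_schedule(opt.global_iter, config)
        _adam_step(model, opt, lr, config)
        opt.global_iter += 1
        row = {
            "task": task.name,
            "iteration": it,
            "lr": lr,
            "loss": loss.item(),
            "ewc_penalty": penalty.item(),
        }
        if (
            config.eval_every
            and task.eval_data
            and (it + 1) % config.eval_every == 0
        ):
            row["eval_mef_ssim"] = evaluate_mef_ssim(model, task.eval_data, mef_params)
        trace.append(row)
    return trace, opt


def evaluate_mef_ssim(
    model: FusionNet, samples, mef_params: MefSsimParams | None = None
) -> float:
    """Mean inference-mode MEF-SSIM of the model's fusions over samples."""
    mef_params = mef_params or MefSsimParams()
    scores = [
        mef_ssim(np.asarray(s["sources"], dtype=np.float64),
                 model.fuse(s["sources"]), mef_params)
        for s in samples
    ]
    return float(np.mean(scores))


def _importance_loss_fn(model: FusionNet, task: TaskSpec, mef_params: MefSsimParams):
    """Per-example task loss (no EWC term) for importance estimation.

    Uses inference-mode normalization so running statistics are untouched.
    """

    def loss_fn(sample):
        sources = np.asarray(sample["sources"], dtype=np.float64)
        fused = model.forward(sources, training=False, clip=False)
        return total_loss(
            fused,
            sources,
            reference=sample.get("reference"),
            ewc_penalty=Tensor(0.0),
            weights=task.weights,
            mef_params=mef_params,
        )

    return loss_fn


def consolidate_task(
    model: FusionNet,
    task: TaskSpec,
    ewc_state: EWCState,
    config: TrainConfig,
    mef_params: MefSsimParams | None = None,
) -> EWCState:
    """Estimate importance on a task subset and fold it into the state."""
    mef_params = mef_params or MefSsimParams()
    rng = np.random.default_rng([config.master_seed % (2**31), task.seed_tag, 999983])
    n = min(task.importance_subset_size, len(task.data))
    idx = rng.choice(len(task.data), size=n, replace=False)
    subset = [task.data[int(i)] for i in idx]
    omega = estimate_importance(
        model.params, subset, _importance_loss_fn(model, task, mef_params)
    )
    anchor = {k: p.data.copy() for k, p in model.params.items()}
    return accumulate(ewc_state, omega, anchor)


def run_curriculum(
    model: FusionNet,
    tasks: list[TaskSpec],
    config: TrainConfig,
    iterations_per_task: int | None = None,
    mef_params: MefSsimParams | None = None,
) -> dict:
    """Train the tasks in order with EWC consolidation between them.

    Returns a report with per-task loss traces and, for every stage, the
    evaluation MEF-SSIM of every task that provides eval data.
    """
    if not tasks:
        raise ValueError("curriculum needs at least one task")
    ewc_state = EWCState()
    report: dict = {"stages": [], "ewc_states": []}

    def snapshot(stage: str):
        scores = {
            t.name: evaluate_mef_ssim(model, t.eval_data, mef_params)
            for t in tasks
            if t.eval_data
        }
        report["stages"].append({"stage": stage, "scores": scores})

    snapshot("initial")
    opt_global_iter = 0
    for task in tasks:
        opt = OptState(global_iter=opt_global_iter)
        trace, opt = train_task(
            model,
            task,
            ewc_state,
            config,
            opt_state=opt,
            iterations=iterations_per_task,
            mef_params=mef_params,
        )
        opt_global_iter = opt.global_iter
        ewc_state = consolidate_task(model, task, ewc_state, config, mef_params)
        report["ewc_states"].append(ewc_state)
        report.setdefault("traces", []).append(trace)
        snapshot(f"after_{task.name}")
    report["final_ewc_state"] = ewc_state
    return report
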