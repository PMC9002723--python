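"""Elastic Weight Consolidation: Fisher-diagonal importance, the anchored
quadratic penalty, and cross-task accumulation.

After a task finishes, the diagonal of the Fisher information matrix is
estimated as the mean element-wise squared gradient of that task's loss
over a small data subset, evaluated at the trained parameters.  During the
next task the penalty eta * sum_i Omega_i (theta_i - theta*_i)^2 pulls
every parameter toward its anchor in proportion to its accumulated
importance.  Importances add across tasks; the anchor is always the most
recently trained parameter vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor

__all__ = ["EWCState", "estimate_importance", "ewc_penalty", "accumulate"]


@dataclass
class EWCState:
    """Anchor parameters, accumulated importance, and the penalty factor.

    ``eta`` defaults to 1 — the task-level EWC weight (the 2×10^4 lambda)
    is applied once by the composite loss, not here, to avoid
    double-counting.
    """

    anchor: dict[str, np.ndarray] = field(default_factory=dict)
    importance: dict[str, np.ndarray] = field(default_factory=dict)
    eta: float = 1.0
    tasks_seen: int = 0

    @property
    def empty(self) -> bool:
        return self.tasks_seen == 0

    def validate_against(self, params: dict[str, Tensor]) -> None:
        if self.empty:
            return
        if set(self.anchor) != set(params) or set(self.importance) != set(params):
            raise ValueError("EWC state layout does not match the model parameters")
        for k, p in params.items():
            if self.anchor[k].shape != p.data.shape:
                raise ValueError(f"EWC anchor shape mismatch for {k!r}")


def estimate_importance(
    params: dict[str, Tensor],
    samples,
    loss_fn,
) -> dict[str, np.ndarray]:
    """Mean element-wise squared gradient of ``loss_fn`` over ``samples``.

    ``loss_fn(sample) -> Tensor`` must evaluate the task loss at the
    current parameters (and must not update normalization running
    statistics).  Parameters are left untouched; only their .grad slots
    are used and cleared.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("importance estimation needs at least one sample")
    acc = {k: np.zeros_like(p.data) for k, p in params.items()}
    for sample in samples:
        for p in params.values():
            p.grad = None
        loss = loss_fn(sample)
        loss.backward()
        for k, p in params.items():
            if p.grad is not None:
                acc[k] += p.grad**2
    for p in params.values():
        p.grad = None
    n = len(samples)
    return {k: v / n for k, v in acc.items()}


def ewc_penalty(params: dict[str, Tensor], state: EWCState):
    """eta * sum_i Omega_i (theta_i - theta*_i)^2 as a differentiable scalar.

    An empty state (no task trained yet) yields exactly zero.
    """
    if state.empty:
        return Tensor(0.0)
    state.validate_against(params)
    total = Tensor(0.0)
    for k, p in params.items():
        omega = state.importance[k]
        if not np.any(omega):
            continue
        diff = p - Tensor(state.anchor[k])
        total = total + (Tensor(omega) * diff * diff).sum()
    return total * state.eta


def accumulate(
    state: EWCState,
    new_importance: dict[str, np.ndarray],
    new_anchor: dict[str, np.ndarray],
) -> EWCState:
    """Fold one finished task into the state (importances add; the anchor
    becomes the latest task's parameters)."""
    if set(new_importance) != set(new_anchor):
        raise ValueError("importance and anchor layouts differ")
    if not state.empty and set(state.importance) != set(new_importance):
        raise ValueError("new task layout does not match the accumulated state")
    merged_importance = {
        k: (state.importance[k] + v if not state.empty else np.array(v, copy=True))
        for k, v in new_importance.items()
    }
    merged_anchor = {k: np.array(v, copy=True) for k, v in new_anchor.items()}
    return EWCState(
        anchor=merged_anchor,
        importance=merged_importance,
        eta=state.eta,
        tasks_seen=state.tasks_seen + 1,
    )
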