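"""The arity-agnostic, permutation-invariant fusion network.

Eight fusion blocks in two phases of four, a three-layer bottleneck
between the phases, mirrored skip connections, and a tail that collapses
the streams into one fused luminance plane.  Every convolution processes
all N input streams with one shared weight set (the *batch mechanism*:
streams are folded into the batch axis), and streams only interact through
an element-wise aggregator — max by default — which is what makes the
output exactly independent of stream order and of stream count.

Per fusion block: a Conv module (3×3 convolution, ReLU, batch
normalization) maps each stream to ``base_channels`` feature planes; the
streams are aggregated element-wise; each stream's own features are
concatenated with the aggregated plane (phase 1: [own | pooled], 2C wide)
and, in phase 2, additionally with a skip from the mirrored phase-1 block
([own | pooled | skip], 3C wide).  Convolutions carry no bias where
normalization follows; the bare convolutions (bottleneck output and tail
output) carry one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._autodiff import (
    Tensor,
    axis_max,
    batch_norm,
    concat,
    conv2d,
    expand_axis,
    no_grad,
)

__all__ = ["NetConfig", "FusionNet", "count_parameters"]


def _default_skip_pairing() -> dict[int, int]:
    # mirrored U-shape: phase-2 block k's concatenation receives the conv
    # output of phase-1 block 9-k (block 5 -> 4, 6 -> 3, 7 -> 2, 8 -> 1)
    return {5: 4, 6: 3, 7: 2, 8: 1}


@dataclass
class NetConfig:
    """Architecture hyper-parameters.

    ``base_channels`` is the per-stream feature width C (32 in the full
    model; smaller for toy-scale experiments).  ``aggregator`` is the
    symmetric stream-pooling function ('max', or 'sum' for ablations).
    ``literal_bn_tail`` switches the final 32→1 convolution to the
    Conv+ReLU+BN form; the default is a bare biased convolution.
    """

    base_channels: int = 32
    kernel: int = 3
    aggregator: str = "max"
    literal_bn_tail: bool = False
    skip_pairing: dict[int, int] = field(default_factory=_default_skip_pairing)
    bn_momentum: float = 0.1
    bn_eps: float = 1e-5

    def __post_init__(self):
        if self.kernel % 2 == 0:
            raise ValueError("kernel must be odd for same-padding")
        if self.aggregator not in ("max", "sum"):
            raise ValueError(f"unknown aggregator {self.aggregator!r}")
        if sorted(self.skip_pairing) != [5, 6, 7, 8] or sorted(
            self.skip_pairing.values()
        ) != [1, 2, 3, 4]:
            raise ValueError("skip_pairing must be a bijection {5..8} -> {1..4}")

    def layer_table(self) -> list[tuple[str, int, int, bool]]:
        """(name, in_channels, out_channels, has_bn) for every conv layer."""
        C = self.base_channels
        rows = [("block1_conv", 1, C, True)]
        rows += [(f"block{k}_conv", 2 * C, C, True) for k in (2, 3, 4)]
        rows += [
            ("bottleneck1", 2 * C, C, True),
            ("bottleneck2", C, C, True),
            ("bottleneck3", C, C, False),
            ("block5_conv", C, C, True),
        ]
        rows += [(f"block{k}_conv", 3 * C, C, True) for k in (6, 7, 8)]
        rows += [("tail1", 3 * C, C, True)]
        rows += [("tail2", C, 1, self.literal_bn_tail)]
        return rows


def count_parameters(config: NetConfig | None = None) -> list[tuple[str, int]]:
    """Trainable-parameter count per layer.

    Convention: a Conv+ReLU+BN row has kH·kW·Cin·Cout kernel weights (no
    convolution bias) plus 2·Cout normalization gain/offset; a bare conv
    row has kH·kW·Cin·Cout + Cout (bias).
    """
    config = config or NetConfig()
    k2 = config.kernel * config.kernel
    return [
        (name, k2 * cin * cout + (2 * cout if has_bn else cout))
        for name, cin, cout, has_bn in config.layer_table()
    ]


class FusionNet:
    """Fusion network with explicit parameter and running-stat dictionaries."""

    def __init__(self, config: NetConfig | None = None, seed: int = 0):
        self.config = config or NetConfig()
        self.params: dict[str, Tensor] = {}
        self.stats: dict[str, np.ndarray] = {}
        rng = np.random.default_rng(seed)
        k = self.config.kernel
        for name, cin, cout, has_bn in self.config.layer_table():
            fan_in = cin * k * k
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, k, k))
            self.params[f"{name}.w"] = Tensor(w, requires_grad=True)
            if has_bn:
                self.params[f"{name}.gamma"] = Tensor(np.ones(cout), requires_grad=True)
                self.params[f"{name}.beta"] = Tensor(np.zeros(cout), requires_grad=True)
                self.stats[f"{name}.running_mean"] = np.zeros(cout)
                self.stats[f"{name}.running_var"] = np.ones(cout)
            else:
                self.params[f"{name}.b"] = Tensor(np.zeros(cout), requires_grad=True)

    # -- building blocks --------------------------------------------------

    def _conv_module(self, x: Tensor, name: str, training: bool, update_stats: bool) -> Tensor:
        """Conv → ReLU → BN (or bare biased conv) applied stream-wise."""
        has_bn = f"{name}.gamma" in self.params
        if has_bn:
            h = conv2d(x, self.params[f"{name}.w"], None, padding="same").relu()
            return batch_norm(
                h,
                self.params[f"{name}.gamma"],
                self.params[f"{name}.beta"],
                self.stats[f"{name}.running_mean"],
                self.stats[f"{name}.running_var"],
                training=training,
                momentum=self.config.bn_momentum,
                eps=self.config.bn_eps,
                update_stats=update_stats,
            )
        return conv2d(x, self.params[f"{name}.w"], self.params[f"{name}.b"], padding="same")

    def _aggregate(self, f: Tensor, groups: int, streams: int) -> Tensor:
        """Pool (G·N, C, H, W) stream features to (G, C, H, W) per group."""
        c, h, w = f.shape[1:]
        r = f.reshape(groups, streams, c, h, w)
        return axis_max(r, 1) if self.config.aggregator == "max" else r.sum(axis=1)

    @staticmethod
    def _tile(pooled: Tensor, groups: int, streams: int) -> Tensor:
        """Broadcast (G, C, H, W) pooled features back to (G·N, C, H, W)."""
        c, h, w = pooled.shape[1:]
        return expand_axis(pooled, streams, 1).reshape(groups * streams, c, h, w)

    # -- forward -----------------------------------------------------------

    def _run(
        self,
        x: Tensor,
        groups: int,
        streams: int,
        training: bool,
        update_stats: bool,
        clip: bool,
    ) -> Tensor:
        """Shared pipeline over G stacks of N streams, folded into the batch."""
        h, w = x.shape[2:]
        skips: dict[int, Tensor] = {}
        for k in (1, 2, 3, 4):
            f = self._conv_module(x, f"block{k}_conv", training, update_stats)
            skips[k] = f
            pooled = self._tile(self._aggregate(f, groups, streams), groups, streams)
            x = concat([f, pooled], axis=1)

        x = self._conv_module(x, "bottleneck1", training, update_stats)
        x = self._conv_module(x, "bottleneck2", training, update_stats)
        x = self._conv_module(x, "bottleneck3", training, update_stats)

        pairing = self.config.skip_pairing
        for k in (5, 6, 7, 8):
            f = self._conv_module(x, f"block{k}_conv", training, update_stats)
            pooled = self._tile(self._aggregate(f, groups, streams), groups, streams)
            x = concat([f, pooled, skips[pairing[k]]], axis=1)

        t = self._conv_module(x, "tail1", training, update_stats)
        pooled = self._aggregate(t, groups, streams)  # (G, C, H, W)
        y = self._conv_module(pooled, "tail2", training, update_stats)
        y = y.reshape(groups, h, w)
        return y.clip(0.0, 1.0) if clip else y

    def forward(
        self,
        streams: np.ndarray | Tensor,
        training: bool = False,
        update_stats: bool | None = None,
        clip: bool = True,
    ) -> Tensor:
        """Fuse an (N, H, W) stack of luminance planes into an (H, W) plane.

        Inference mode (the default) normalizes with running statistics, so
        the output is bit-for-bit invariant to stream order and unaffected
        by duplicated streams.  Output clipped to [0, 1]; optimization
        passes ``clip=False`` so gradients at saturated pixels survive (the
        hard clip would zero them, hiding those weights from both training
        and importance estimation).
        """
        x = streams if isinstance(streams, Tensor) else Tensor(streams)
        if x.ndim != 3:
            raise ValueError("expected an (N, H, W) stack of luminance planes")
        n, h, w = x.shape
        if n < 1:
            raise ValueError("need at least one input stream")
        if h < self.config.kernel or w < self.config.kernel:
            raise ValueError("input smaller than the convolution kernel")
        if update_stats is None:
            update_stats = training
        x = x.reshape(n, 1, h, w)
        return self._run(x, 1, n, training, update_stats, clip).reshape(h, w)

    __call__ = forward

    def fuse(self, streams: np.ndarray) -> np.ndarray:
        """Inference-mode fusion returning a plain (H, W) array."""
        with no_grad():
            return self.forward(np.asarray(streams, dtype=np.float64)).data

    def fuse_many(self, stacks: np.ndarray, max_batch_streams: int = 32) -> np.ndarray:
        """Inference-mode fusion of G same-arity stacks at once.

        ``stacks``: (G, N, H, W).  Equivalent to calling :meth:`fuse` on
        each stack (inference normalization is per-sample), but one pass;
        chunked so at most ``max_batch_streams`` streams are in flight.
        """
        stacks = np.asarray(stacks, dtype=np.float64)
        if stacks.ndim != 4:
            raise ValueError("expected a (G, N, H, W) array of stacks")
        g, n, h, w = stacks.shape
        step = max(1, max_batch_streams // n)
        outs = []
        with no_grad():
            for i in range(0, g, step):
                chunk = stacks[i : i + step]
                gc = chunk.shape[0]
                x = Tensor(chunk).reshape(gc * n, 1, h, w)
                outs.append(
                    self._run(x, gc, n, training=False, update_stats=False, clip=True).data
                )
        return np.concatenate(outs, axis=0)

    # -- parameter plumbing -------------------------------------------------

    def named_parameters(self) -> dict[str, Tensor]:
        return self.params

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {f"param/{k}": v.data for k, v in self.params.items()}
        out.update({f"stat/{k}": v for k, v in self.stats.items()})
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for k, p in self.params.items():
            p.data = np.array(arrays[f"param/{k}"], dtype=np.float64)
        for k in self.stats:
            self.stats[k] = np.array(arrays[f"stat/{k}"], dtype=np.float64)

    def save(self, path, extra: dict[str, np.ndarray] | None = None) -> None:
        """Write a single .npz checkpoint: weights, running stats, config."""
        arrays = self.state_arrays()
        if extra:
            arrays.update({f"extra/{k}": np.asarray(v) for k, v in extra.items()})
        cfg = asdict(self.config)
        cfg["skip_pairing"] = {str(k): v for k, v in cfg["skip_pairing"].items()}
        arrays["config_json"] = np.frombuffer(
            json.dumps(cfg).encode(), dtype=np.uint8
        )
        np.savez(Path(path), **arrays)

    @classmethod
    def load(cls, path) -> tuple["FusionNet", dict[str, np.ndarray]]:
        """Load a checkpoint; returns (model, extra-arrays)."""
        with np.load(Path(path)) as zf:
            arrays = {k: zf[k] for k in zf.files}
        cfg = json.loads(bytes(arrays.pop("config_json")).decode())
        cfg["skip_pairing"] = {int(k): v for k, v in cfg["skip_pairing"].items()}
        model = cls(NetConfig(**cfg))
        model.load_state_arrays(arrays)
        extra = {
            k.removeprefix("extra/"): v
            for k, v in arrays.items()
            if k.startswith("extra/")
        }
        return model, extra
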