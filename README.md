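# nfuse

Permutation-invariant fusion of an arbitrary number of co-registered images
— multi-focus stacks, bracketed exposures, infrared/visible pairs, MRI/PET
pairs — into one composite, with continual learning across those tasks.

## The problem and the model

Classical learned fusion networks accept a fixed number of inputs (usually
two) and fuse larger sets recursively, losing the joint view of all sources.
`nfuse` instead treats the sources as an unordered *set*. The network
realizes the symmetric decomposition

&nbsp;&nbsp;&nbsp;&nbsp;f(X) = γ( maxᵢ φ(xᵢ) )

where φ is a convolutional feature extractor applied to every input stream
with one shared weight set, max is taken element-wise across the streams in
feature space, and γ reconstructs the fused image. Because max is symmetric
and all streams share weights, the output is *exactly* independent of input
order and count: the same trained model fuses 2 or 8 images, reordering the
inputs changes nothing (bit-for-bit), and duplicated inputs are ignored.
The architecture is eight fusion blocks in two phases with mirrored skip
connections, a convolutional bottleneck, and a stream-collapsing tail; each
block pools the streams by max and concatenates the pooled plane back onto
every stream's own features.

Training spans several fusion tasks sequentially with Elastic Weight
Consolidation (EWC): after each task the Fisher-diagonal importance
Ωᵢ = E[(∂L/∂θᵢ)²] is estimated on a small data subset, and later tasks pay a
penalty ΣᵢΩᵢ(θᵢ−θᵢ\*)² for moving important parameters away from the anchor
θ\*. Tasks with a reference image (multi-exposure, multi-focus) minimize
0.5·MAE + 0.5·(1−MEF-SSIM) + 2×10⁴·L_ewc; tasks without one (medical,
infrared/visible) use the no-reference MEF-SSIM loss alone plus the penalty.
RGB inputs are fused in the luminance channel only; chroma is fused by the
weighted rule Cf = ΣCᵢ(Cᵢ−τ)/Σ(Cᵢ−τ) (τ = 128, neutral where the
denominator vanishes).

A synthetic data module generates multi-focus training sets (binary
complementary masks composed from basal partitions and free-form shape
masks; defocus via Dᵢ = I_clear·Pᵢ + I_blur·(1−Pᵢ), σ ∈ [1,2]) and bracketed
exposure stacks from latent radiance maps, so the whole pipeline builds,
trains at toy scale, and tests without any external dataset. See
`docs/methods.md` for the full model description and design choices.

## Worked example

Train the fusion network on synthetic multi-focus sets and fuse a held-out
defocused stack:

```python
import numpy as np
from nfuse import FusionNet, NetConfig, mef_ssim
from nfuse.experiments import make_focus_task
from nfuse.trainer import TrainConfig, train_task
from nfuse.ewc import EWCState

task = make_focus_task(seed=1)                      # 16 train / 8 eval sets, 32x32
model = FusionNet(NetConfig(base_channels=8), seed=1)
cfg = TrainConfig(master_seed=1, patch=32, initial_lr=1e-3)
trace, _ = train_task(model, task, EWCState(), cfg, iterations=300)
print(f"training loss: {trace[0]['loss']:.3f} -> {trace[-1]['loss']:.3f}")

sample = task.eval_data[0]
fused = model.fuse(sample["sources"])               # (H, W) luminance in [0, 1]
print(f"held-out MEF-SSIM of the fused image: {mef_ssim(sample['sources'], fused):.3f}")
print(f"MAE against the all-in-focus ground truth: {np.abs(fused - sample['reference']).mean():.4f}")
```

Output (about half a minute on one CPU):

```
training loss: 1.083 -> 0.056
held-out MEF-SSIM of the fused image: 0.911
MAE against the all-in-focus ground truth: 0.0526
```

The fused image scores higher than either defocused source alone (0.865 and
0.886 on the same stack): the network recovers sharp content from whichever
source is in focus at each location, and lands within ~5% mean absolute
error of the all-in-focus ground truth after only 300 iterations at toy
scale.

The same workflow is available from the shell:

```sh
nfuse synth --n-sets 8 --size 128 --seed 7 --out data/focus      # synthetic dataset
nfuse train --config train.yaml --seed 7 --out runs/demo         # curriculum + EWC
nfuse fuse data/focus/set_0000 --checkpoint runs/demo/checkpoint_multi_focus.npz --out fused.png
nfuse eval --data data/focus --checkpoint runs/demo/checkpoint_multi_focus.npz --out report.csv
```

Checkpoints are single `.npz` archives holding the weights, normalization
running statistics, the network configuration (JSON), and optionally
optimizer/EWC state under an `extra/` namespace; `FusionNet.load` restores
them exactly.

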