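# Methods

## The fusion model

`nfuse` fuses a *set* of N co-registered images of one scene into a single
composite. The core design constraint is that a fusion operator should be a
function of the set, not the sequence: reordering the inputs must not change
the result, and the same trained weights must serve any N. The network
realizes the set-function decomposition f(X) = γ(maxᵢ φ(xᵢ)): a shared
per-stream feature extractor φ, an element-wise max across the set in feature
space, and a reconstruction head γ. Because max is symmetric and every stream
passes through identical weights, permutation-invariance is exact by
construction — not approximate — and the tests assert bit-identical outputs
under reordering and under duplicated streams.

Concretely, the network has eight *fusion blocks* in two phases of four, a
three-layer bottleneck between them, and a tail:

- A fusion block applies a Conv module (3×3 convolution → ReLU → batch
  normalization) to each stream with shared weights, pools the streams
  element-wise (max), and concatenates each stream's own features with the
  pooled plane ([own 32 | pooled 32] in phase 1, plus a 32-channel skip from
  the mirrored phase-1 block in phase 2, giving 96 channels).
- The bottleneck is Conv+ReLU+BN 64→32, Conv+ReLU+BN 32→32, and a bare
  biased convolution 32→32.
- The tail reduces 96→32 per stream, max-pools across streams once more, and
  reconstructs the fused plane with a final 32→1 convolution clipped to
  [0, 1].

Channel widths scale with `base_channels` (default 32; toy experiments use
8). Parameter-count conventions: convolutions followed by normalization carry
no bias (counts 352 / 18,496 / 27,712 / 9,280 for the 1→32, 64→32, 96→32 and
32→32 rows); bare convolutions carry one (9,248 for 32→32). The final
1-channel layer is a bare biased convolution by default (289 parameters);
`literal_bn_tail=True` restores a Conv+ReLU+BN tail for comparison, though
normalizing a 1-channel output is unusual. The skip pairing is the mirrored
U-shape (phase-1 block k feeds phase-2 block 9−k's concatenation; the first
phase-2 block takes no skip at its input, which is what makes its input width
32); it is stored in `NetConfig` so alternatives remain testable.

### Numerical choices

- All computation is float64 on a small hand-rolled reverse-mode autodiff
  core (`nfuse._autodiff`): im2col convolution, batch normalization, set-max
  with ties routed to the first attaining stream, and two sliding-window
  primitives for the structural loss. Gradients are verified against central
  finite differences at 1e-4 relative tolerance or better.
- Batch normalization folds the N streams into the batch axis (statistics
  pool over streams and space), momentum 0.1, epsilon 1e-5; the running
  variance stores the biased batch estimator. Inference normalizes with
  running statistics — this, not an approximation, is what makes inference
  outputs exactly permutation-invariant and duplication-idempotent (training
  mode is invariant only up to float summation order).
- The [0, 1] clip is applied at inference only. During optimization the loss
  sees the unclipped output: a hard clip zeroes the gradient at saturated
  pixels, which both stalls learning there and — more insidiously — hides
  those weights from the Fisher importance estimate used for consolidation
  (they would look unimportant precisely where they are critical).
- N = 1 is accepted (the set function degenerates gracefully; useful for
  identity tests) although fusion proper needs N ≥ 2.

## Losses

Supervised tasks (multi-exposure, multi-focus — a reference exists) minimize
λ₁·MAE + λ₂·(1 − MEF-SSIM) + λ₃·L_ewc with λ₁ = λ₂ = 0.5 and λ₃ = 2×10⁴.
Unsupervised tasks (medical, infrared/visible) use λ₁·(1 − MEF-SSIM) +
λ₂·L_ewc with λ₁ = 1, λ₂ = 2×10⁴, and zero EWC weight for the first task
trained. A config check warns when the EWC weight leaves [1×10⁴, 3×10⁴], the
range in which results are insensitive to it.

MEF-SSIM scores a fused image against the source set without a reference.
Per 8×8 sliding window (stride 1): each source patch is decomposed into mean,
contrast c = ‖x − x̄‖ and unit structure s = (x − x̄)/c; the desired patch
takes the largest contrast among sources and a structure direction from a
weighted average of the sources' structures, weights cᵖ (p = 4, frozen in
`MefSsimParams`; the identities tested hold for any p ≥ 0). The per-window
score is the structure-only similarity (2·cov + C)/(σ²₁ + σ²₂ + C) between
the desired patch and the mean-removed fused patch, C = (0.03·L)² with L the
unit dynamic range; the final score is the window mean. Windows where every
source is constant contribute 1 when the fused patch is also constant and are
otherwise penalized through ε-regularized norms (ε = 1e-12). The score is
differentiable in the fused image; the sources enter only through constant
per-window targets.

## Continual learning

Tasks are trained sequentially. After each task, the Fisher-diagonal
importance Ωᵢ = mean over a data subset of (∂L/∂θᵢ)² is estimated at the
trained parameters using that task's own loss (no EWC term, inference-mode
normalization so running statistics are untouched); importances accumulate
additively across tasks and the anchor θ\* is always the latest trained
parameter vector. While a later task trains, the penalty η·ΣΩᵢ(θᵢ − θᵢ\*)²
(η = 1 inside the penalty; the 2×10⁴ task weight is applied exactly once by
the composite loss) pulls parameters toward the anchor in proportion to their
importance. The squared form is used throughout; it is the only version
bounded below. The importance subset defaults to 50 examples per task.

Normalization statistics need special care: they are not trainable, so the
quadratic penalty cannot anchor them, yet inference depends on them. Left
free, they drift to the new task's statistics and destroy the consolidated
behavior even with weights pinned (we measured exactly this failure mode).
Therefore, whenever a non-empty consolidation state is active, later tasks
train in the frozen-statistics regime: normalization uses the stored running
statistics, gradients flow through them as constants, and the statistics are
never updated again. The first task trains normally.

Optimization is Adam (β₁ = 0.9, β₂ = 0.99), batch size 1, 128×128 crops,
learning rate 1e-4 halved every 5×10⁴ iterations. Adam moments reset per
task; the iteration counter for the schedule runs across the curriculum.
Every sample draw and crop is keyed by (master seed, task, iteration), so
training is bit-reproducible and a run resumed from a checkpoint (weights,
running statistics, Adam state) retraces the uninterrupted trajectory
exactly. The default task order is infrared/visible → medical →
multi-exposure → multi-focus with 200/300/270/3 epochs; the order is
configurable.

## Synthetic data

Multi-focus training sets are simulated because all-in-focus ground truth is
otherwise unavailable. A clear image is Gaussian-blurred with σ drawn
uniformly from [1, 2] per set (kernel radius ⌈3σ⌉, reflective borders);
binary complementary masks Pᵢ partition the frame; the i-th defocused image
is Dᵢ = I_clear·Pᵢ + I_blur·(1 − Pᵢ). Masks come from coarse *basal*
partitions of the frame (1 part; left/right halves; vertical thirds;
quadrants) intersected with a free-form *shape mask* (ellipse-like, wavy
polygon, or smoothed-noise blob; connected; 15–60% coverage; a library of
213 procedural shapes), then deterministically merged/split to the requested
M ∈ [2, 8] parts, each holding at least 1% of the pixels. Two identities hold
exactly and are asserted on every generated set: ΣPᵢ = 1 per pixel, and
ΣDᵢ·Pᵢ = I_clear (so oracle mask-selection achieves MAE 0 — the upper-bound
baseline for any fusion network).

Clear images are procedural broadband textures (directional gradient,
random figures, band-passed noise) standing in for photographic crops.
Exposure stacks render a latent radiance map (dynamic range ≈ 100:1) at K
geometric gains with clipping at the bright end only, plus a Reinhard
tone-mapped reference; the lowest exposure never clips, so every pixel is
observed unclipped somewhere in the stack. These generators are deliberately
minimal: they contain no sensor noise, no gamma encoding, no motion, no
misregistration. Consequently the exposures of one stack are exact scalar
multiples of each other wherever unclipped — informationally far more
redundant than real bracketed photographs. Passing tests on this data
demonstrate the mechanics (invariances, optimization, consolidation), not
real-photograph fusion quality.

## Toy-scale experiments

`nfuse.experiments` runs two directional studies sized for minutes on one
CPU: an 8-channel network, 32×32 images, 16 training and 8 held-out sets per
task, 300 iterations per task, three seeds. The toy runs use learning rate
1e-3 — at a few hundred iterations the full-scale 1e-4 leaves the model near
its initialization, making comparisons between training regimes meaningless;
full-scale defaults are unchanged.

- **Retention.** Train exposure, consolidate, then train focus twice from
  the same snapshot — with and without the EWC penalty. With consolidation
  the exposure-task quality drop after the second task is several times
  smaller, in every seed tested (`retention_*` in the acceptance output).
- **Pooling ablation.** Identical training with max vs sum aggregation,
  run on both toy tasks. On the *multi-focus* task, where sources are
  complementary (each sharp somewhere else), max wins decisively. On the
  *multi-exposure* task the two are statistically indistinguishable
  (differences ~0.01–0.03 in either direction across seeds): because the
  synthetic exposures are scalar multiples of one radiance map, selective
  pooling has no advantage over additive pooling there. A max-over-sum
  margin on exposure data of the kind seen on real stacks is below what
  these study conditions can resolve; the acceptance suite asserts it
  anyway and reports the measured outcome honestly (`pooling_*`).

## Known limitations

- No GPU path and float64 only: full-scale (3000-set, 128×128, hundreds of
  epochs) training is out of reach; the package targets correctness and
  desk-scale studies.
- The chroma rule fuses Cb/Cr by signed deviation-from-neutral weighting;
  when deviations cancel exactly the neutral value is used (tolerance 1e-8
  on the accumulated denominator). Saturated color edges can alias under
  this rule; it is the standard companion to luminance-only fusion.
- 16-bit RGB PNG writing is not supported by the PNG backend; use TIFF.
- The defocus simulator applies one σ per set and spatially uniform blur —
  no depth-dependent point-spread functions or bokeh.
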