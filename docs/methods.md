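# Methods

This note documents the models and procedures implemented in `serpensgate`,
the choices made where the published material leaves the design open, and
what the synthetic benchmark does and does not show.

## The detector

The network is a YOLOv8-style one-stage, anchor-free detector described by a
24-row layer table: a five-stage stride-2 convolutional backbone, a top-down
/ bottom-up feature-pyramid neck, and a decoupled detection head reading the
stride-8/16/32 maps. Three non-standard blocks sit at the deepest scale:

* **C2f with dynamic snake convolutions** (layer 8). Each bottleneck's second
  3×3 convolution is replaced by a three-branch block: a standard k×k
  convolution, and two *snake* convolutions whose k sampling points lie along
  a continuity-constrained path. An offset head (3×3 conv → batch norm →
  tanh) predicts 2k bounded offsets per pixel: an *elastic* component
  stretches each unit step along the morph axis (x = along width, y = along
  height) to 1 + e_j, and a *drift* component accumulates on the
  perpendicular axis. Accumulation runs from the kernel centre outward, so
  |coord(j+1) − coord(j) − 1| < 1 always — the path cannot tear. Sampling is
  bilinear with coordinates clamped to the map (replicate behaviour at
  borders); with the offset head zeroed each branch reduces exactly to an
  axis-aligned 1×k / k×1 convolution, which the tests assert.
* **SPPELAN** (layer 9). A 1×1 projection to a pyramid width, three cascaded
  5×5 stride-1 max pools (receptive fields 5/9/13), 4-way concatenation and a
  1×1 fuse. Shape-preserving by construction.
* **Super-token attention** (layer 10). Tokens X ∈ R^{N×C} (N = H·W) are
  summarised by m grid-initialised super tokens; one soft-k-means pass
  computes a sparse row-stochastic association Q = softmax(X Sᵀ/√d) over each
  token's 3×3 super-token neighbourhood (d = C) and updates S = Q̂ᵀX with Q̂
  the column-normalised Q. Multi-head self-attention (4 heads) runs over the
  m super tokens only; tokens are reassembled as X′ = Q·S_att and added
  residually. One sampling pass costs 19NC flops (NC init + 9NC association
  + 9NC update). The block's parameters are a bias-free 1×1 qkv projection
  (3C²), a biased output projection (C² + C) and two frozen 3×3 unfold/fold
  kernels (2×81, non-trainable).

### Parameter accounting

`count_params` counts conv weights and batch-norm scale/shift as trainable;
batch-norm running statistics are bookkeeping, not parameters; the DFL
projection (16 bin indices) and the attention unfold/fold kernels (162) are
fixed. Under this convention the assembled model reproduces the printed
per-layer count of all 20 structurally forced table rows exactly, and its
fixed-parameter total is 178 — equal to the published difference between the
"parameters" and "gradients" summary lines. The four remaining rows (the
backbone C2f blocks and the snake C2f) use internally modified layouts whose
printed counts are not derivable from any published description; the audit
reports these as *known-divergent* with both numbers side by side rather
than hiding the gap. (The printed per-layer column also does not sum to the
printed total, so exact reconciliation is impossible even in principle.)

Choices that the printed counts force: batch-norm statistics excluded,
stride-1 same-padded pooling in SPPELAN, head widths c2 = max(16, ch₀/4,
4·reg_max) and c3 = max(ch₀, min(nc, 100)), reg_max = 16. Choices they do
not constrain: SiLU activations, group normalisation (C/4 groups) in the
snake branches, 4 attention heads, one sampling iteration, a 5×5 attention
grid cell (m = 16 on the 20×20 map; non-divisible extents get ceil-sized
edge cells).

### A caveat on translation equivariance

The attention block treats all positions identically, but on a finite map
the border cells have truncated 3×3 neighbourhoods; because the attention
over super tokens is global, these border effects reach every output token,
so equivariance under cyclic translation holds only approximately (deviations
of order 10⁻² on 8×8 maps). The symmetry that holds exactly — and is tested —
is mirror equivariance, since mirroring maps borders onto borders.

## The tensor engine

The package runs on its own reverse-mode autodiff engine over float32 numpy
arrays: im2col convolution (with a pointwise fast path), fused batch norm,
stride-1 max pooling, nearest ×2 upsampling, batched matmul, and a bilinear
sampler differentiable in both features and coordinates. Every operator is
gradient-checked against central finite differences, and convolution values
against an independent correlation oracle. Determinism: identical weights
and inputs give bit-identical outputs in a fixed-precision single-threaded
run; all randomness flows through explicitly seeded generators.

## Training

Loss = 7.5·box + 0.5·cls + 1.5·dfl, the conventional detector weighting.

* **Box**: Wise-IoU, L = r · R_wiou · (1 − IoU) with
  R_wiou = exp(d²/(W_g² + H_g²)) over the smallest enclosing box (denominator
  detached), outlier degree β = (1 − IoU)/mean(1 − IoU) against a detached
  running mean, and focusing factor r = β / (δ·α^(β−δ)), α = 1.9, δ = 3 —
  the v3 focusing form, which is the published pairing for these two
  hyperparameter values; r = 1 at β = δ.
* **Cls**: binary cross-entropy against task-aligned soft targets.
* **DFL**: cross-entropy spread over the two bins adjacent to each target
  side distance.

Assignment is task-aligned top-k (alignment = score^0.5 · IoU^6, k = 10,
centre-inside, ties to the highest alignment; deterministic). The default
`TrainConfig` is the published recipe: 500 epochs, batch 8, SGD
(momentum 0.937, weight decay 5e-4), lr 1e-2 → 1e-4, NMS IoU 0.7, mosaic
1.0 with the collage disabled for the final 10 epochs, flip 0.5, translation
0.1, scale 0.5, 640² inputs.

## The synthetic leaf-lesion benchmark

`synth.generate_leaf_scene` emulates the traits that make in-field disease
imagery hard: cloudy textured backgrounds, 1–4 wavy leaf shapes, lesions
drawn as thick constant-curvature random walks (total turn 2.2–4.5 rad, so
arc/chord > 1.2 on average — the curved geometry snake kernels target),
global lighting gain and gradient, and occluding foreground strips applied
*after* boxes are captured, so labels stay consistent by construction (a
provenance oracle scores mAP@0.5 = 1.0). Six classes: three lesion types
distinguished by colour and stroke style, three healthy leaf shapes.

It does **not** model: photorealistic plant tissue, intra-class texture
variety approaching real foliage, label noise, or class imbalance. Passing
the desk benchmark therefore demonstrates that the full pipeline (blocks,
assembly, assignment, losses, optimiser, decoding, NMS, metrics) can drive a
detector from random weights to useful accuracy on CPU; it says nothing
about accuracy on real field imagery, which the published experiments
address with GPU-scale training on an external dataset and which is out of
scope here.

## The desk profile

CPU-scale experiments use 256×256 scenes (250 scenes: 200 train / 50 val by
the deterministic 8:1:1 split with val and test pooled), a width-0.375
variant of the assembled graph (channels 8→96, reg_max 8, ≈0.7M parameters)
and a 30-epoch recipe: mosaic off (tiny single-object-scale datasets
converge faster without collage), warm-up 3 epochs, lr 1e-2 decaying to
1e-3, otherwise the published settings. With seed 7 this reaches
mAP@0.5 ≈ 0.56 on the validation split in about 7 minutes on one CPU; the
per-class APs show the elongated-leaf class as the hardest. Loss curves and
the best/last checkpoints are written as JSON-lines and `.npz`.

## Evaluation conventions

Boxes are pixel xyxy; detections match greedily in confidence order at
IoU ≥ 0.5, one match per ground truth; AP integrates the all-point
(right-max) interpolated precision envelope; mAP is the plain mean over
classes with at least one ground truth or detection. Precision/recall are
pooled counts; the headline report carries both the F1 of the pooled P/R
pair and a macro-averaged per-class F1, which generally differ. The
confusion matrix uses class-agnostic greedy IoU matching with an extra
background row/column. Grad-CAM weights a captured layer's activations by
the spatial mean of the class-score gradient, rectifies, normalises to
[0, 1] and upsamples.
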