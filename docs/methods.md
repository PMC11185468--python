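# Methods

## Problem and approach

A class activation map (CAM) explains one prediction of an image classifier
as a 2-D saliency map built from one layer's channel activations

    L^c(A^l) = ReLU( combine_k( α_k^c , A_k^l ) ),

where `A^l = f^l(x)` are the `k` channel maps of layer `l` and the weights
`α` are scheme-specific.  In practice only the final layer or two are
visualized, and picking *which* layer to trust is usually arbitrary.  This
package instead computes the CAM at **every** target layer `l = 0..N-1`,
renders the ordered stack as an animation, and scores each layer's map with
the combined Remove-and-Debias (ROAD) perturbation metric.  The resulting
per-layer ROAD series — ybROAD — makes layer selection quantitative: its
argmax is the most faithful explanatory layer, and its mean summarizes how
well the network's maps identify the class evidence end to end.

## Target layers

A *target layer* is a leaf module whose forward output is a numeric tensor,
excluding pure pass-throughs (identity, inference-mode dropout); the census
is configurable through an `include_filter` predicate.  A probe forward pass
classifies each layer's output shape:

- `spatial2d` — at least two trailing spatial axes of extent > 1; renderable.
- `vector1d` — rank ≤ 2 outputs, or spatial outputs collapsed to 1×1.  A 2-D
  rendering of a 1-D vector is meaningless (single neurons paint lines
  across the frame), so these layers are excluded from rendering and ROAD
  scoring, logged once each, and still reported in the sidecar CSV.
- `token_sequence` — rank-3 batch × tokens × embedding outputs.  These are
  rendered only when the caller supplies a token-grid reshape rule (H, W),
  since no universal token-to-grid rule exists.

Layers executed more than once per forward pass contribute one frame, taken
from their final invocation, so the layer axis stays well defined.  Models
are always run in inference mode (frozen normalization statistics, no
stochastic layers); every capture is therefore bit-deterministic, and
capturing never mutates parameters.

Gradients for the CAM weights are of the **pre-softmax logit** of the target
class, standard in the gradient-CAM literature; ROAD confidences use the
**post-softmax probability**.  The target class is resolved once (integer or
argmax on the unperturbed image) and held fixed across all layers and all
perturbations.

## Weighting schemes

The scheme definitions are pinned exactly, with ε = 1e-8 and softmax
temperature 1, so independent implementations can agree:

| scheme | weights |
|---|---|
| gradcam | α_k = spatial mean of G_k; map = Σ α_k A_k |
| gradcam++ | α_k = Σ_ij w_kij ReLU(G_kij), w = G² / (2G² + Σ_ab A G³ + ε) |
| xgradcam | α_k = Σ_ij (A_kij / (Σ_ab A_kab + ε)) G_kij |
| hirescam | map = Σ_k G_k ⊙ A_k |
| gradcam_elementwise | map = Σ_k ReLU(G_k ⊙ A_k) |
| layercam | map = Σ_k ReLU(G_k) ⊙ A_k |
| eigencam | first right singular vector of A reshaped (k × HW); sign so Σ ≥ 0; class-agnostic |
| eigengradcam | eigencam applied to G ⊙ A |
| scorecam | α = softmax over channels of the target logit on image ⊙ min-max-scaled upsampled A_k |
| ablationcam | α_k = (y^c − y^c_{k ablated}) / (\|y^c\| + ε) |
| randomcam | α_k ~ Uniform(−1, 1), seeded |

Rectification is applied **before** bilinear upsampling to input resolution
(the difference from rectifying after is minor but had to be pinned; it is a
known source of small discrepancies between CAM implementations).  The
upsampler is corner-aligned bilinear interpolation, so constant maps stay
constant and 2×2 → 4×4 has a closed form used as a test oracle.  ScoreCAM
with all-constant channels defines its weights as zero rather than dividing
by a degenerate range.

## Local vs global normalization

Local normalization rescales each frame by its own (min, max) — "what does
this layer attend to?".  Global normalization rescales every frame by the
single (min, max) over all frames — "which layer matters most overall?" —
so weakly activating layers appear as attenuated versions of their local
maps.  Constant frames (and all-equal stacks) normalize to zero with a
logged warning.  Skipped 1-D layers never enter the global extrema, since
they are never rendered.  Rendering overlays `(1−α)·image + α·colormap(map)`
with a jet-like default colormap and α = 0.5 (both configurable), stamps
the layer caption, and is a pure deterministic function of its inputs.
Frames are written as zero-padded PNGs and encoded to MP4 at 10 fps by
default; when no H.264 encoder is present the encoder falls back to an
equivalent GIF with a warning.

## ROAD and the layer-wise series

For a unit-scaled map, `select_pixels` takes exactly `round(p·H·W)` pixels
by saliency rank (ties broken by ascending flat index, so a constant map
selects the first indices deterministically).  Noisy linear imputation
replaces the selected pixels by the solution of the sparse linear system in
which each imputed pixel equals the **uniform mean of its in-bounds
4-neighbours** (unmasked neighbours enter as constants), solved per channel
with a sparse direct solver, after which Gaussian noise (default
sd = 0.01 on unit-scaled intensities, applied after solving, imputed pixels
only) removes any residual mask-shape signal.  The 4-neighbour uniform
stencil is a deliberate dialect — some formulations weight diagonal
neighbours — chosen because it admits an exact dense-solver oracle; a
`neighbor_weighting` tag records the contract.  A fully masked image is
ill-posed and falls back to a channel-mean fill with a warning.  Unmasked
pixels are always bit-unchanged.

At fractions p ∈ {0.2, 0.4, 0.6, 0.8} and both orderings, the confidence
change is `C = p(target | imputed) − p(target | original)` (the baseline
convention is configurable to raw probability).  The combined score
aggregates `(C_LRP − C_MRP)/2` over fractions.  **Aggregation defaults to
the mean**, not the sum: with mean aggregation each score is bounded in
[−1, 1] and per-layer values are comparable across configurations with
different fraction counts; `aggregate="sum"` remains available.  Noise
draws are seeded per (fraction, semantic ordering), which makes the metric's
antisymmetry exact: exchanging which ordering fills the LRP and MRP slots
negates the combined score bit-for-bit.

ROAD is computed on the locally normalized map; ranking is invariant to any
monotone rescaling, so this choice only fixes the contract.  ybROAD runs
the scorer over every `spatial2d` target layer in forward order and reports
the series, its mean, max and argmax layer, plus the skipped layers.

## The synthetic test-bed

No pretrained weights or external data are used anywhere.  The fixtures
module emulates a malignant-vs-normal ultrasound classification task at
desk scale: 64×64 single-channel images, echo-poor background (level 0.25),
Gaussian-smoothed multiplicative speckle (noise level 0.15, σ = 1.5),
per-image gain jitter, and class-independent clutter — one to three bright
elongated fascia-like bands and up to two dark shadow bands — present in
both classes.  The positive class adds a compact filled elliptical lesion
(semi-axes 8–16 px) raised by the configured contrast (default 0.4); clutter
never overlaps lesion support, so in the noiseless limit lesion pixels sit
exactly at background + contrast.  The clutter is what makes the task
non-trivial: overall brightness is not class evidence, the lesion is, which
is exactly the structure needed for saliency faithfulness to be measurable.
Datasets are class-balanced, split 80–10–10 (stratified), and bitwise
reproducible from (parameters, seed).

The paired classifier is a 3-block CNN — conv3×3 (8/16/32 channels) +
batch-norm + ReLU + max-pool per block, then global average pooling and a
2-class linear head — 15 target layers (12 spatial), 6,066 parameters.
Training uses Adam (lr 1e-2, batch 32) for 10 epochs on n = 400 by default,
reaching ≥ 0.9 held-out accuracy in well under a minute on one CPU.

What the fixture does **not** model: real speckle statistics (Rayleigh
envelopes), depth-dependent attenuation, operator variability, anatomical
diversity, or any augmentation pipeline.  Passing tests therefore shows the
machinery is correct and that the qualitative behaviors hold on a task with
the right causal structure — not that any specific clinical model is
faithful.

## Problem sizes and known limitations

- The quantitative suite runs ybROAD on 12 layers × 4 fractions × 2
  orderings (96 imputations and forward passes per series, each a ≤ 3,300
  unknown sparse solve); a full series takes ~1.5 s.  Seeded robustness
  checks use 10 trials each.  The trained-vs-untrained accuracy check runs
  at n = 200 / 5 epochs per seed; the canonical model everywhere else uses
  the n = 400 / 10 epoch defaults.
- Trained maps on this fixture saturate near 0.5 under mean aggregation
  (a confident 2-class model loses essentially all probability once the
  lesion is imputed), so mean ybROAD of a well-trained fixture is large
  (~0.35–0.5) while a random-weights twin sits at ~0.
- RandomCAM's near-zero mean holds on the canonical seed (≈ 0.07 averaged
  over 10 seeded trials) but individual trained fixtures can retain a
  positive bias (up to ~0.2 for some training seeds): with only 8–32
  channels on a single-lesion task, channels stay partially
  lesion-correlated, so random positive combinations sometimes rank the
  lesion highly.  Large many-class models do not share this small-scale
  artifact.
- Zoo architecture specs census **parameter-bearing** leaves only
  (convolutions, norms, linear/scale/bias terms); parameter-free activation
  and pooling layers are omitted, so `n_target_layers` for a zoo profile
  counts censused leaves, not renderable layers.  The totals are exact for
  the standard 1000-class configurations.
- Degenerate frames (an everywhere-non-positive weighted map rectifies to a
  constant zero) normalize to zeros with a warning and select their
  perturbation pixels by the deterministic tie-break; their ROAD score is
  then noise-level near zero, which is the sensible value for an
  uninformative frame.
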