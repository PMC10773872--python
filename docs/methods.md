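# Methods

## Problem and model

`glandseg` implements binary semantic segmentation of prostate adenocarcinoma
in H&E-stained tissue: every pixel of an RGB patch is classified as benign (0)
or malignant (1), where the malignant class is the union of Gleason pattern 3
(discrete well-formed glands) and pattern 4 (fused glands) — the early,
clinically decisive patterns. Three encoder–decoder families are trained and
fused:

* **U-Net** — forward convolutional units (two 3×3 convolutions, each
  followed by batch normalization and ReLU) with plain skip concatenation;
* **AU-Net** — the same units, with each skip connection gated by an additive
  attention gate: α = σ(ψ(ReLU(Wₓ·x↓ + W_g·g))), upsampled and multiplied
  onto the skip feature, where g is the coarser decoder signal;
* **ARU-Net** — residual convolutional units (conv path plus an identity or
  1×1-projection shortcut; the unit output is the plain sum of the two
  branches, with no activation after the addition) combined with the same
  attention gates.

The prediction head is a 1×1 convolution to two channels followed by a
per-pixel softmax, yielding an H×W×2 probability field; the predicted label
is the per-pixel argmax (ties resolve to benign).

### Training objective

The loss is `total = dice + 1·focal`, with

* a class-weighted soft F_β ("Dice") term built per class from soft
  confusion counts TP_c = Σ y_c·p_c, FP_c = Σ (1−y_c)·p_c,
  FN_c = Σ y_c·(1−p_c): F_β = ((1+β²)·P·R + s) / (β²·P + R + s), and
  loss = Σ_c ŵ_c (1 − F_β(c)) with the class weights ŵ normalized to sum 1
  (so rescaling all weights is a no-op);
* a binary focal term on the malignant-probability channel,
  mean(−y·α(1−p)^γ·log p − (1−y)·α·p^γ·log(1−p)), natural log,
  probabilities clipped to [1e−7, 1−1e−7]. The balancing factor α multiplies
  *both* terms, so γ=0, α=1 recovers plain binary cross-entropy exactly.

Defaults: β=1, α=0.25, γ=2, smooth=1e−5, focal multiplier 1. These symbols
are conventional for F-score and focal losses; all are configuration keys.
The smoothing constant appears symmetrically in numerator and denominator so
that a perfect hard prediction scores exactly zero loss.

Class weights default to pixel-level inverse-frequency balancing over the
training masks, w_c = N_total / (2·N_c); a patch-level basis is available as
a switch. A training set with roughly 27% malignant pixels yields weights
near (0.68, 1.85), the regime this pipeline is designed for.

### Evaluation metrics

Jaccard = (I + s)/(U + s) with I = Σ y·p, U = Σy + Σp − I, computed on soft
probabilities or hard masks. Two Dice forms exist because the source
formulation divides by the *union*, which exceeds 1 at perfect overlap
(21/11 for two identical 10-pixel masks at s=1). Both are implemented: the
"literal" form for fidelity and the conventional 2I/(Σy+Σp) form, which is
the reporting default since published Dice scores ≤ 1 imply it. Mean IoU is
the unweighted two-class mean of TP/(TP+FP+FN) from one-vs-rest confusion
tables; a class absent from both fields contributes 1.0 by the smoothing
convention (configurable).

### Ensembling and comparison

The model ensemble (ME) averages the three per-model softmax vectors pixel
by pixel; the weighted ensemble (WME) uses a weighted mean with weights
normalized by their sum — the reference weight tuples (e.g. 0.0/0.2/0.4) do
not sum to 1, and normalization leaves the argmax unchanged while keeping
the output a probability field. Weights are found by exhaustive grid search
over {0, 0.2, …, 1}³ minus the all-zero tuple (215 candidates), scored by
validation mean IoU; ties resolve to the lexicographically smallest tuple.
Because every one-hot tuple is in the grid, the optimum never scores below
any single model.

Methods are compared with a two-tailed paired t-test, t = mean(d)/(sd(d)/√n)
with sample sd (n−1), p from Student's t with df = n−1. What constitutes a
paired observation is a genuine design choice: here each of k seeded repeats
(default 3) scores every method on the same random half of the validation
patches, giving matched per-repeat mean-IoU observations. Identical methods
produce zero-variance differences, for which t is undefined and an error is
raised (the pipeline records such pairs as NaN).

## Preprocessing

Annotations are polygons labeled with an 11-class taxonomy (Bg, Fg, N, GP3,
GP4, GP5, L, NE, NS, PIN, Blood; codes 0–10). Rasterization paints pixels
whose centers fall inside a polygon, later polygons overwriting earlier
ones. Binarization maps GP3∪GP4 → 1, everything else → 0.

Patch quality control keeps a patch iff (a) its tissue ratio ≥ 0.2 and (b)
its label raster contains at least one non-Bg/Fg pixel — dropping patches of
pure background, pure foreground, or their mixtures. "Tissue ratio" is
operationally defined here as the fraction of pixels whose minimum RGB
channel is ≤ 220/255 (standard whiteness masking); whether the published
20% threshold was measured on the image or the annotation mask is ambiguous,
so both bases are exposed (`ratio_basis="image"|"mask"`, image default).
Patch grids are 0-based (row, col) with half-open pixel ranges and default
stride = patch size (non-overlapping), which makes extraction exactly
invertible by score-map assembly.

NE ("not evaluated") and NS ("not sure") pixels map to class 0 by default;
they are benign for loss and metric purposes, consistent with a screening
tool that should not be rewarded for flagging unannotated tissue.

## Synthetic data

No public dataset accompanies the task, so the generator emulates the
*structure* of annotated biopsy material, not its appearance statistics:
pink stroma, white lumina, purple epithelial rings with dark nuclear
speckle, plus additive Gaussian RGB noise (σ = 8/255). Benign glands are
few large thick rings with open lumina; GP3-like tissue is many small
discrete rings; GP4-like tissue is fused masses of overlapping blobs.
Malignant epithelium is rendered darker with denser nuclear speckle — a
stylized version of hyperchromasia — so the toy task carries color and
texture cues a small network can learn quickly. `crowding` sets the target
gland area fraction; the empirical malignant fraction tracks a requested
value within ±0.1. Toy slides place elliptical tissue cores with
region-level labels; their label raster is produced by rasterizing the very
polygons returned to the caller, so the annotation round trip is exact by
construction.

Consequences for interpretation: passing tests show the pipeline's
machinery — losses, gradients, ensembling, reconstruction — is correct and
that the architectures can fit a gland-like segmentation task; they say
nothing about performance on real WSIs, stain variation, scanner artifacts,
or the hard benign/GP3 boundary that requires immunohistochemistry in
practice.

## Training regime

Adam (β₁=0.9, β₂=0.999) with initial learning rate 1e−4, up to 100 epochs,
batch size 16, and validation Jaccard monitored each epoch; on a plateau of
`lr_patience` epochs (default 5) the rate is multiplied by 0.5, floored at
1e−6, and the best-validation-Jaccard state (weights *and* batch-norm
running statistics) is restored at the end. Masks enter as complementary
2-channel encodings matching the softmax head. No augmentation by default.

The networks, their gradients, and Adam are implemented in numpy (im2col +
BLAS matmul convolutions, float32 parameters), so fixed seeds give
bit-reproducible runs without any backend determinism flags.

The bundled desk-scale study — used by the test suite and the acceptance
script — trains depth-3, base-8 variants on 256 synthetic 64×64 pairs for
15 epochs at learning rate 1e−3. The raised rate is the package's scaling
choice: the desk run takes ~240 optimizer steps versus ~145,000 at full
scale, and 1e−4 would leave all three families visibly under-converged
within 15 epochs. Default widths double per level from `base_filters`
(16 at depth 5 for the full-scale configuration); batch normalization is on
by default, and convolutions preceding it carry no bias so that every
parameter receives gradient. Upsampling is 2× nearest-neighbour followed by
a 3×3 convolution (avoids transposed-convolution checkerboard artifacts);
the attention gates' inner width is half the skip channels.

## Slide maps

Per-patch malignant probabilities are mosaicked back into their grid cells.
Cells removed by quality control are *missing* (NaN), rendered as the bare
slide — a filtered patch is an absent observation, not a confident benign
call; a zero-fill mode exists for comparability. Overlays alpha-blend a
dark-green→yellow→red colormap (cool = low, hot = high probability) and a
color-bar strip is emitted alongside. If overlapping strides are ever used,
covering predictions would need averaging; the default pipeline never
overlaps.

## Numerical choices and degenerate inputs

* Probability clipping at 1e−7 in the focal log terms; gradients pass only
  inside the clip range.
* Softmax uses the max-shift trick; its backward is the closed-form
  Jacobian–vector product.
* Argmax ties break to class 0 everywhere; grid-search ties break to the
  lexicographically smallest tuple; both are deterministic.
* Empty masks: Jaccard/Dice of two empty masks is 1 by the smoothing
  convention; a class absent from the training set makes inverse-frequency
  weights undefined and raises with advice to pass explicit weights.
* Dice loss is computed globally over the batch (not per image); a
  per-image option would change scores on heterogeneous batches.

## Known limitations

Single-resolution toy slides only (no pyramidal WSI formats, magnification
handling, or stain normalization); binary labels only (no Gleason scoring or
grade groups); the numpy backend is CPU-bound and sized for small studies,
not for 10⁵-patch datasets; recurrent convolutional units and pre-trained
backbones are out of scope.
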