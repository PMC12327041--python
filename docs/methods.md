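# Methods

## Problem

Leaf instance segmentation for rosette plants (Arabidopsis-like top-view
imagery): every pixel of an RGB image is assigned to background (0) or to
one of K individual leaves (1..K).  The hard parts are leaf–leaf occlusion
and petioles 1–3 px wide.  The package follows the pixel-embedding
paradigm: a network maps the image to an E-dimensional embedding per pixel,
a discriminative loss shapes the embedding so pixels of one leaf cluster
tightly while clusters of different leaves repel, and instances are
recovered at inference by mode-seeking (mean shift) in embedding space.

## Network

The encoder has four downsampling stages (each halves the resolution):

* **GR stage** (shallow): three parallel branches — 2×2 max-pool → 3×3
  conv, and two stride-2 1×1 convs followed by asymmetric 1×3 / 3×1 convs —
  concatenated to a map `H`; then a cross-residual pair
  `M = ReLU(C33(H) + C11(H))`, `F = ReLU(C33(M) + C11(H))` (the second sum
  reaches back over `M` to `H`).
* **WGR stages** (×3, deeper): one max-pool branch and three stride-2 1×1
  branches (two expanded into 1×3/3×1 pairs, one through an extra 3×3),
  concatenated to a six-way map `g`, fused by
  `ReLU(C33(C33(g)) + C11(g))`.
* **OT block** (top stage refinement): 1×1 token embedding to dimension D;
  4 outlooker layers (multi-head outlook attention over 3×3 neighborhoods,
  pre-norm residuals); 2×2 patch flattening with a linear projection and a
  learned positional table; 12 transformer self-attention layers; bilinear
  re-expansion and 1×1 projection back to the stage width, so the block
  preserves its input shape and can be ablated transparently.

Skip connections ("R-Skip") keep one fusion node per level:
`S3 = F3`, `S2 = C11([F2, up2(S3)])`, `S1 = C11([F1, up2(F2), up2(S2)])`,
with bilinear ×2 upsampling.  The decoder fuses multi-scale upsampled
high-level maps into every shallow step ("Muti-UP"):

    Y3 = C33([up2(Y4), S3])
    Y2 = C33([up2(Y3), up4(C11(Y4)), S2])
    Y1 = C33([up2(Y2), up4(C11(Y3)), up8(C11(Y4)), S1])
    Y0 = C33(up2(Y1))

The printed decoder recursion does not consume the skip outputs; we
concatenate `S_i` into the step of matching resolution, the only reading
that uses them.  A final 1×1 conv maps `Y0` to E = 8 embedding channels
(no activation).  Ablation flags remove the OT block (config I), replace
skips + decoder by a plain UNet-style chain (II), drop only the multi-scale
laterals (III), or only the skip reconstruction (IV); V is the full model.

### Conventions and numerical choices

* Every convolution is followed by batch normalization (eps 1e-5, momentum
  0.1, no conv bias); ReLU only where a block definition calls for it.
  Decoder 3×3 fusions use ReLU; 1×1 skip/lateral fusions do not.
* One stride-2 1×1 conv inside the GR residual is read as stride-1 — the
  only shape-consistent reading of the block definition.
* "Same" zero padding at stride 1; asymmetric kernels pad only along their
  long axis.  Max pooling is 2×2 stride 2; ties broken by first occurrence.
* Bilinear resampling uses the half-pixel-center convention, frozen so the
  tests can assert bit-exact values.
* Outlook attention: per-location K²×K² logits are softmaxed, restricted to
  in-bounds neighbors and renormalized; the overlapping windows are
  fold-accumulated and divided by the per-pixel overlap count.  Both
  normalizations make a constant token grid an exact fixed point of the
  aggregation, which plain zero-padded sum-folding violates at borders.
* All computation is float32; a float64 input array stays float64 through
  the pure loss functions so oracle comparisons run at full precision.

### Channel plan

The publication reports only total parameter budgets, never widths.  The
reference plan — stage widths (64, 160, 320, 640), GR branch 32, WGR
branches (40, 80, 182), token dim 728 with 8 heads, outlooker/transformer
MLP hidden 2187/2162, skip widths (82, 160), decoder (320, 160, 80, 40)
with lateral width 76, plain decoder (308, 160, 81, 40) — was calibrated
once against the three published budgets (104.45 M for the full model,
19.14 M without the attention block, 103.87 M with plain skips/decoder)
and is frozen.  The two un-calibrated ablations land at 104.11 M and
104.33 M against published 104.12 M / 104.21 M, which supports the plan's
plausibility.  MAC counts use 1 MAC per multiply-add in conv/linear/
attention products, ignoring normalizations, activations, pooling and
resampling; absolute MAC figures are therefore convention-dependent and
informational.

## Loss

For ground-truth instances c = 1..C with pixel embeddings x_i and means
mu_c:

* variance: mean over instances of mean over pixels of
  `[||mu_c − x_i|| − δ_v]₊²` (default δ_v = 0.5),
* distance: mean over ordered pairs of `[2δ_d − ||mu_a − mu_b||]₊²`
  (default δ_d = 1.5; zero when C = 1, where the pair set is empty),
* regularizer: mean of `||mu_c||`,

combined as `α·L_var + β·L_dist + γ·L_reg` with α = β = 1, γ = 0.001.  The
norm is L2 by default (L1 available).  Background participates as one
extra cluster by default, so the single printed objective yields both
foreground/background separation and instance separation; the margins are
configurable because their experimental values were never printed.

## Instance recovery

Mean shift (flat kernel, bandwidth δ_v) seeded on a regular pixel subgrid
(every 4th pixel; density estimated from every 2nd pixel — the embedding
field is spatially smooth, so subsampling preserves the modes).  Modes are
deduplicated within one bandwidth by the mean-shift step itself; then
low-support modes within `merge_radius` of a stronger mode are attached to
it.  The merge threshold follows from the loss geometry: fragments of one
instance lie within ~2δ_v = 1.0 of each other, while a mode of a different
instance is at least 2δ_d − δ_v = 2.5 away, so any threshold in (1.0, 2.5)
separates the cases; the default 2.0 = δ_v + δ_d is mid-band.  Attachment
is greedy and non-transitive (modes are ordered by support), so a diffuse
cluster cannot chain two genuine instances together.  Pixels are assigned
to the nearest kept mode within `assign_radius` (default 2δ_v), clusters
below `min_instance_pixels` (default 16) dissolve to background, the
cluster owning the majority of image-border pixels maps to label 0
(rosettes are plant-centered; a largest-cluster rule is available), and
labels are renumbered 1..K by decreasing size.

## Synthetic rosettes

The generator emulates the traits that make the real benchmarks hard:
1–20 elliptical leaves radiating from a common center, petioles 1–3 px
wide connecting each blade to the center, later leaves occluding earlier
ones (visible-partition labels, as in real 2-D annotation), per-leaf green
shade variation, a global illumination gradient with jitter, soil-like
textured background, and Gaussian blur (σ = 0.8 by default — blur makes
the leaf/background transition a genuine mixture band, which is the main
difficulty the recovery stage faces).  It does not emulate venation or
leaf texture, specularities, growth sequences, or amodal masks; passing
tests therefore demonstrate the pipeline's mechanics and its robustness to
occlusion, thin structures and smooth photometric variation, not
performance on real phenotyping images.  Generation is deterministic per
seed; an unfittable request (too many/too large leaves for the frame) is
rejected after a bounded number of layout attempts.

## Training

AdamW (decoupled weight decay 0.05), lr 1e-3, batch 16, 200 epochs and an
85/15 train/validation split by default; the lr decays by 0.1 on a
validation plateau (patience 10) because the published decay factor comes
without a trigger; reduce-on-plateau is the common pairing.  Model
selection keeps the best validation score (instance SBD when computed,
otherwise validation loss).  Augmentation: random crop and random
vertical/horizontal flips applied jointly to image and labels.  All
randomness (init, data order, augmentation) derives from one seed; two
runs with the same seed produce identical loss traces.  Training aborts
with a diagnostic on non-finite loss.

### Desk-scale property

The acceptance suite trains a reduced model (widths ÷ 4, outlook depth 1,
transformer depth 2, E = 8) for 14 epochs on 200 synthetic 64×64 rosettes
(2–6 leaves, overlap factor 0.3) and requires mean SBD ≥ 80 and mean
|DiC| ≤ 1 on 40 held-out images for each of three seeds.  The problem
sizes (14 epochs, batch 16, 64×64) are chosen so the property demonstrates
end-to-end learning on a single CPU core; with these settings each seed
trains in a few minutes (the worked example in the README shows the
numbers one such run prints).

## Known limitations

* The headline benchmark scores of the original study (CVPPP/KOMATSUNA/
  MSU-PID) require the external datasets and GPU-scale training of the
  104 M-parameter model for 200 epochs; they are out of scope here and
  nothing in this package asserts them.
* The OT block's positional table binds a built model to one input size.
* Mean-shift recovery assumes the margins used in training; if δ_v/δ_d are
  changed, the clustering defaults should be scaled with them.
* The backward pass stores full intermediate maps; memory, not compute, is
  the limit for batched training of the full-width model on large inputs.
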