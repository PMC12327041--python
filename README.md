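# grotunet

Leaf instance segmentation for rosette plants via discriminative pixel
embeddings.

Plant phenotyping needs per-leaf masks and leaf counts from top-view
images, but rosette leaves overlap, occlude each other and hang on
petioles only 1–3 px wide.  This package implements an encoder–decoder
network — parallel-branch/cross-residual convolutional stages, an
outlooker + transformer attention refinement of the top stage,
reconstructed one-node-per-level skip connections and a multi-scale
upsampling-fusion decoder — that maps an RGB image to an E-dimensional
embedding per pixel.  Training minimizes the discriminative loss

    L = α·L_var + β·L_dist + γ·L_reg

    L_var  = (1/C) Σ_c (1/N_c) Σ_i [ ||μ_c − x_i|| − δ_v ]₊²
    L_dist = (1/C(C−1)) Σ_{a≠b} [ 2δ_d − ||μ_a − μ_b|| ]₊²
    L_reg  = (1/C) Σ_c ||μ_c||

(α = β = 1, γ = 0.001, δ_v = 0.5, δ_d = 1.5 by default) so that pixels of
one leaf collapse toward their mean μ_c while means of different leaves
repel.  Instances are recovered by mean-shift clustering in embedding
space; maps are scored with the field's standard metrics — foreground–
background Dice (FBD), Symmetric Best Dice (SBD) and the difference in
count (DiC, |DiC|).  A seeded generator of synthetic rosette images with
instance labels serves as the test bench, so everything runs end-to-end on
one CPU with no external data.  The numerical stack (network, reverse-mode
autodiff, AdamW) is implemented in numpy inside the package.

## Worked example

Generate a synthetic dataset, train a desk-scale model, and score it:

```python
import numpy as np
import grotunet as g

spec = g.RosetteSpec(image_size=(64, 64), n_leaves=(2, 6),
                     leaf_axis_range=(8, 18), overlap_factor=0.3, seed=100)
g.write_dataset("data/train", g.generate_dataset(spec, 200))
held = g.RosetteSpec(image_size=(64, 64), n_leaves=(2, 6),
                     leaf_axis_range=(8, 18), overlap_factor=0.3, seed=9000)
g.write_dataset("data/held", g.generate_dataset(held, 40))

cfg = g.TrainConfig(model=g.reduced_config(), batch_size=16, epochs=14, seed=0)
model, log = g.train(cfg, "data/train")
report = g.evaluate(model, "data/held", seed=0)
print({k: round(v, 2) for k, v in report.means.items()})
```

On one CPU core this trains in a few minutes and prints

```
{'fbd': 88.14, 'sbd': 87.33, 'dic': 0.0, 'abs_dic': 0.0}
```

meaning the held-out foreground mask overlaps the truth at Dice ≈ 88 %,
the per-leaf masks reach a symmetric best Dice of ≈ 87 %, and the
predicted leaf count is exact on average (DiC 0, |DiC| 0).

The same pipeline is available from the shell:

```sh
grotunet synth --n 200 --size 64 --seed 7 --leaves 2,6 --out data/train
grotunet train data/train --reduced --seed 0 --out runs/demo
grotunet eval runs/demo/checkpoint.npz data/held
grotunet predict runs/demo/checkpoint.npz data/held --out preds/
grotunet score data/held preds/
grotunet params            # parameter/MAC accounting for configs I..V
```

`grotunet params` reports the frozen reference architecture at 256×256×3:
104.45 M parameters for the full model (config V), 19.14 M without the
attention block (I), 103.87 M with plain UNet-style skips/decoder (II).

## Layout

| module | contents |
| --- | --- |
| `grotunet.nn` | numpy reverse-mode autodiff, layers, AdamW |
| `grotunet.blocks` | GR / WGR encoder blocks, outlook attention, OT block |
| `grotunet.model` | full network, ablation variants I–V, parameter/MAC accounting, checkpoints |
| `grotunet.loss` | discriminative embedding loss |
| `grotunet.cluster` | mean-shift instance recovery |
| `grotunet.metrics` | FBD, Best Dice, SBD, DiC and reports |
| `grotunet.synthetic` | rosette generator, augmentations, dataset I/O, splits |
| `grotunet.train` | training/evaluation/prediction pipelines |
| `grotunet.cli` | `grotunet` command-line interface |

See `docs/methods.md` for the model conventions, the channel-plan
calibration, the clustering geometry and known limitations.
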