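# mildnet

Semantic segmentation of biomedical images — skin lesions in dermoscopy,
neuronal membranes in electron microscopy, tumors in MRI, glands in
histopathology, cell nuclei in microscopy — with **MILDNet**, a U-Net
extended by multi-level dilated residual blocks and residual-of-residual
skip connections. The package is aimed at researchers who want the full
method — architecture, training protocol, evaluation metrics, saliency
interpretation and significance testing — as a reproducible,
CPU-runnable library with a bundled synthetic-data generator, so every
part of the pipeline can be exercised without downloading clinical
datasets.

## The model

MILDNet keeps the classical U-Net skeleton: an encoder of `depth = 5`
resolution stages whose filter widths double per stage
(`[32, 64, 128, 256, 512]`), 2×2 stride-2 max pooling between stages, a
mirrored decoder driven by 2×2 stride-2 transposed convolutions, skip
connections from each encoder stage to its decoder counterpart, and a
1×1 convolution head with a sigmoid producing a per-pixel foreground
probability. Two substitutions define the method:

**MLDR blocks** replace every double-convolution stage. Each block
stacks `N = 2` pre-activation residual levels

```
y_L = h(x_L) + F(x_L, W_L),    x_{L+1} = f(y_L)
```

where `h` is the identity (a 1×1 projection when the channel count
changes), `f` is ReLU, and `F` is one BN → ReLU pre-activation followed
by three parallel 3×3 *dilated* convolutions at rates `d = 1, 3, 5`,
fused by element-wise sum. A dilated kernel spaces its taps `d` pixels
apart, so its receptive field is `k + (k−1)(d−1)` — 3, 7 and 11 pixels
for the three branches — letting one block see regions of interest at
several scales at once. An outer shortcut from the block input to the
second level's output makes the block *residual-of-residual*.

**MLR blocks** sit on every skip connection. Same two-level
residual-of-residual structure, but each level is BN → ReLU followed by
two sequential standard 3×3 convolutions; channel counts are preserved.
Processing the skip tensor non-linearly before concatenation narrows
the semantic gap between shallow encoder features and deep decoder
features.

Training minimizes mean binary cross-entropy computed from logits;
evaluation reports the Dice coefficient `DC = 2|Y∩Ŷ|/(|Y|+|Ŷ|)`, the
Jaccard index `IoU = |Y∩Ŷ|/|Y∪Ŷ|` and the symmetric Hausdorff distance
`HD = max(h(Y,Ŷ), h(Ŷ,Y))` over foreground pixel sets under the
Euclidean metric. The data protocol is: min-max intensity scaling to
[0, 1], bilinear resize to 256×256, optional 256-pixel patching with
16-pixel reflect padding for small datasets, an image-level 70/30
train/test split, 5-fold cross validation inside the training portion
(each fold's model is scored on the one fixed test set), paired
geometric + photometric augmentation, gradient saliency maps averaged
over decoder stages for interpretation, and a paired t-test on per-fold
IoU for model comparison.

## Worked example

```python
import numpy as np
from mildnet import (ArchitectureConfig, TrainingConfig, SyntheticProfile,
                     build_network, generate_samples, make_split_plan,
                     train_model, evaluate_model)

profile = SyntheticProfile(regime="clean", image_size=(64, 64),
                           contrast=0.9, noise_sd=0.05, seed=1)
samples = generate_samples(profile, 64)
plan = make_split_plan([s.id for s in samples], seed=1)   # 19 test, 45 train
by_id = {s.id: s for s in samples}

arch = ArchitectureConfig(variant="mildnet", depth=3, initial_filters=8)
model = build_network(arch, seed=1)
cfg = TrainingConfig(epochs=15, batch_size=4, seed=1)
model, history = train_model(model, [by_id[i] for i in plan.train_ids()],
                             [by_id[i] for i in plan.validation_ids()], cfg)
report = evaluate_model(model, [by_id[i] for i in plan.test_ids])
print(report.format_aggregate())
```

which prints (for this seed):

```
  DC: 0.9953 ± 0.003908
 IOU: 0.9907 ± 0.007721
  HD: 0.9692 ± 0.4074
```

— mean ± standard deviation over the 19 held-out test images: 99.5%
Dice overlap, and predicted boundaries about one pixel from the truth
on average. The same protocol is available from the shell:

```bash
mildnet generate --regime clean --n 64 --size 64 --out data/
mildnet split --manifest data/manifest.csv --seed 1 --out plan.json
mildnet cv --manifest data/manifest.csv --plan plan.json --out runs/cv
mildnet compare --a 0.92,0.93,0.91,0.92,0.94 --b 0.88,0.90,0.89,0.87,0.91
```

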