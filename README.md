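# camagree

**How reliable are class-activation maps as weak segmentations of
soft-boundary tissue damage?**

Class-activation maps (CAMs) are the standard route to weakly supervised
semantic segmentation (WSSS): train an image-level classifier, extract the
regions most discriminative for the positive class, threshold them into a
mask.  For objects with crisp edges this works reasonably well.  For
biological tissue damage -- for example muscle transformation after
freezing and thawing, imaged by T2-weighted MRI -- the damaged region has a
*soft boundary*: it fades gradually into healthy tissue, pixel-level ground
truth is ill-defined, and different CAM methods may disagree wildly about
what is "damaged".

`camagree` is a toolkit for quantifying exactly that disagreement.  It
provides:

* a **synthetic generator** of paired fresh/damaged grayscale image stacks
  with per-pixel soft-boundary damage ground truth and a liquid-loss
  percentage coupled to the true damage fraction (an external damage proxy,
  emulating drip loss after freeze--thaw);
* **preprocessing**: background masking (max filter, erosion, Gaussian
  blur, 2-means intensity clustering), augmentation (rotation <= 45°,
  flips, <= 20% shifts, contrast stretching, histogram equalisation,
  CLAHE), and sample-level 80/10/10 splitting that avoids slice leakage;
* a **CNN classifier backend** -- a compact reverse-mode-autodiff CNN
  engine over numpy with three desk-scale architecture families (plain
  stack, residual, multi-branch) that exposes pre-softmax scores, named
  layer activations `A_k`, and class-score gradients `dY^(c)/dA_k`;
* five **CAM methods**: Grad-CAM, Grad-CAM++, Score-CAM, Faster Score-CAM,
  and Layer-CAM, with shared post-processing (bilinear upsampling, [0,1]
  normalisation, binarisation over a threshold grid `t_CAM`);
* **agreement statistics**: IoU and mIoU against a reference segmentation,
  cross-method agreement `phi_m` and cross-model agreement `phi_c` (mean
  pairwise IoU normalised by `1/C(n,2)`), Spearman rank correlation with
  liquid loss, and Kruskal--Wallis group tests;
* a **CLI pipeline** (`camagree all --config run.yml`) with resumable,
  content-hash-cached stages.

## The statistics at the core

With `C` the set of CAM methods and `M` the set of CNN models, the per-slice
agreement across CAM methods for a fixed model `m` at threshold `t_CAM` is

    phi_m = (1 / C(|C|,2)) * sum_{i<j} IoU(mask(C_i, m), mask(C_j, m))

and symmetrically `phi_c` fixes the CAM method and varies the model.  Both
lie in [0, 1]; a value near 1 means the binarised heatmaps nearly coincide.
Two empty masks score IoU 1 by default (both agree on "no damage");
`both_empty="exclude"` drops such pairs instead.  Liquid loss is
`LL% = 100 * (m0 - mL) / m0` for initial and final sample masses, and its
synthetic counterpart is drawn as `LL = base + slope * damage_fraction +
noise`.

## Worked example

```python
import numpy as np
import camagree
from camagree import backend, cam, agreement, preprocess, pipeline

# 20 heavily damaged samples (severity 0.9), 8 slices each, 64x64
cfg = camagree.GeneratorConfig(n_samples_per_group=20, treatment_levels=(0.9,), seed=0)
samples = camagree.generate_dataset(cfg)
split = preprocess.split_by_sample(samples, seed=0)
parts = pipeline._partition_arrays(samples, split)

model = backend.build_model("plain", seed=0).astype(np.float32)
result = backend.train(model, parts["train"], parts["val"], seed=0)
print("validation accuracy:", result.best_val_accuracy)

s = samples[0]
img = s.damaged_slices[0].image * s.foreground_masks[0]     # background removed
heat = cam.grad_cam(model, img)                             # damaged class y=1
mask = cam.binarize(heat, 0.5, foreground=s.foreground_masks[0])
print("IoU vs ground truth:", agreement.iou(mask, s.truth_masks[0]))
```

prints (numbers from this exact run):

```
validation accuracy: 0.96875
IoU vs ground truth: 0.5446650124069479
```

The classifier separates fresh from damaged slices almost perfectly
(mirroring the near-perfect accuracies such models reach on real
freeze-thaw MRI), and the Grad-CAM mask at `t_CAM = 0.5` overlaps the
ground-truth damage far better than chance: across all 160 damaged slices
of this run the Grad-CAM mIoU is 0.59 versus 0.23 for area-matched random
masks.

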