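# glandseg

Segmentation of colon glands in H&E-stained histopathology images, and
whole-image benign/malignant classification, combining two pixel-wise CNN
classifiers with a globally optimal weighted-total-variation (wTV)
figure-ground segmentation.  The package also implements the GlaS-style
object-level evaluation metrics and a synthetic H&E-like scene generator so
that every stage can be exercised and tested without any external dataset.

## Who this is for

Researchers in computational pathology who want a transparent, CPU-only
reference implementation of the classic two-network + convex-segmentation
pipeline for gland instance segmentation: preprocessing by color
deconvolution, pixel classification by sliding-window CNNs, instance
extraction by geodesic-active-contour-style convex energy minimization, and
object-level evaluation.

## The method

1. **Preprocessing.** The RGB image is separated into stain densities with
   the Ruifrok–Johnston optical-density model (`OD = -log10(I/255)`,
   inverted through a unit-norm stain matrix; the "H&E 2" preset by
   default).  The hematoxylin channel is kept, contrast-normalized with
   CLAHE, and downsampled to half resolution for classification.

2. **Pixel classification.** Two LeNet-style CNNs with K = 7 weighted
   layers read 101×101 patches and classify the center pixel:
   the *Object-Net* into four classes — benign background (C₀), benign
   gland (C₁), malignant background (C₂), malignant gland (C₃) — and the
   *Separator-Net* into gland-separating structure vs. not.  Both are
   trained by minibatch SGD with momentum, weight decay and dropout, with
   early stopping on a validation set.

3. **Refinement.** Class maps are fused into figure/ground probabilities

   ```
   p_fg = max{(I_C1 + I_C3) − S, 0},   p_bg = min{(I_C0 + I_C2) + S, 1}
   ```

   so that separator evidence S carves corridors between touching glands.

4. **Segmentation.** The relaxed field u ∈ [0,1] minimizes the convex
   energy

   ```
   E(u) = ∫ g(x)|∇u(x)| dx + λ ∫ u(x) w(x) dx,
   g = exp(−α‖∇I‖^β),   w = ∓ logit of the dominant class probability
   ```

   (w = 0 where the confidence stays below τ), solved to its global
   optimum with a first-order primal–dual scheme and thresholded at 0.5.
   Hole filling, a 500-px minimum area and connected-component labeling
   yield gland instances.  Defaults: α = 10, β = 0.95, λ = 0.1, τ = 0.65.

5. **Classification.** The image-level decision is the argmax of the
   spatially averaged benign (C₀+C₁) vs. malignant (C₂+C₃) probabilities;
   the winning average is the decision confidence.

6. **Evaluation.** Detection F1 at 50% object overlap, pixel and
   area-weighted object-level Dice, and object-level Hausdorff distance,
   plus accuracy / class-wise precision, recall and F1 for the
   benign/malignant decision.

## Worked example

```python
import numpy as np
from glandseg import (
    SceneConfig, generate_scene, generate_probability_fixtures,
    segment_from_maps, classify_tissue, evaluate_image,
)
from glandseg.pipeline import preprocess_image

# a synthetic H&E-like scene: 5 benign glands with full ground truth
image, labels, separators = generate_scene(
    SceneConfig(seed=3, n_glands=5, shape=(192, 192))
)
# simulated classifier outputs (blurred one-hot maps) stand in for the CNNs
maps, sep_map = generate_probability_fixtures(labels, separator=separators,
                                              blur=1.0, seed=0)
channel, _ = preprocess_image(image)
segmentation, field = segment_from_maps(maps, sep_map, channel, min_area=200)
decision = classify_tissue(maps)
scores = evaluate_image(labels.pixels, segmentation.pixels)
print(segmentation.n_objects, decision.label,
      round(scores["f1"], 3), round(scores["object_dice"], 4))
```

prints

```
5 benign 1.0 0.9998
```

— all five glands are recovered (detection F1 = 1.0) with an area-weighted
object-level Dice of 0.9998 against the ground truth, and the image is
classified benign.

A command-line interface mirrors the library
(`glandseg synth / preprocess / sample / train / predict / segment /
classify / evaluate / tune`); every run writes a `manifest.json` with the
configuration hash and seeds needed to reproduce its outputs.

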