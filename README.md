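# arkfcm

Adaptively regularized kernel-based fuzzy C-means clustering for brain MR
tissue segmentation.

Soft clustering of T1-weighted brain slices into cerebrospinal fluid (CSF),
gray matter (GM) and white matter (WM) is a standard first step in
neuroimage analysis, but plain fuzzy C-means (FCM) classifies each pixel by
its intensity alone and falls apart under the noise and smooth intensity
nonuniformity (bias field) typical of MR acquisition. This package
implements an FCM variant that is robust to both, by combining

* a **per-pixel adaptive regularizer** φᵢ derived from the local variation
  coefficient (LVC) of the grayscales in a small window, and
* a **Gaussian radial basis function (GRBF) kernel distance** in place of
  squared Euclidean distance, with the kernel width σ estimated from the
  image itself.

It ships with the evaluation metrics used to validate such segmentations
(per-class Jaccard similarity and an entropy-based quality measure *E*) and
a synthetic brain-slice phantom generator with ground truth, so the whole
pipeline can be exercised without any external dataset.

## Model

Each foreground pixel *i* with grayscale *xᵢ* receives a fuzzy membership
*uᵢⱼ* in every cluster *j* with center *vⱼ*, minimizing

```
J = Σᵢ Σⱼ uᵢⱼ^m [ ‖Φ(xᵢ) − Φ(vⱼ)‖² + φᵢ ‖Φ(x̄ᵢ) − Φ(vⱼ)‖² ],
‖Φ(a) − Φ(b)‖² = 2 (1 − K(a, b)),      K(a, b) = exp(−(a−b)² / 2σ²),
```

subject to Σⱼ uᵢⱼ = 1. Here x̄ᵢ is a locally smoothed grayscale; choosing
the 3×3 **average** filter, the **median** filter, or a φ-weighted blend of
each pixel with its neighborhood mean (the **weighted image** ξ̄) gives the
three variants ARKFCM₁, ARKFCM₂ and ARKFCM_w. The regularization weight

```
φᵢ = 2 + ωᵢ  if x̄ᵢ < xᵢ,    2 − ωᵢ  if x̄ᵢ > xᵢ,    0  if x̄ᵢ = xᵢ,
```

with ωᵢ a softmax (over the window) of the summed neighbor LVC values,
adapts the strength of spatial smoothing to the local heterogeneity:
homogeneous regions get none, noisy regions get more. Minimization
alternates a fixed-point center update with the closed-form membership
update until the largest membership change falls below ε = 0.001 (at most
100 iterations).

## Worked example

```python
import numpy as np
from arkfcm import (ClusterConfig, PhantomSpec, arkfcm_segment,
                    generate_phantom, jaccard_per_class)

phantom = generate_phantom(PhantomSpec(
    shape=(128, 128), geometry="slice_like",
    noise_model="rician", noise_level=10.0, seed=42,
))
result = arkfcm_segment(phantom.image, ClusterConfig(variant="median"))
print(f"sigma = {result.sigma:.2f}, iterations = {result.n_iter}, "
      f"converged = {result.converged}")
print("centers:", np.round(result.partition.centers, 1))
scores = jaccard_per_class(result.labels, phantom.truth, [1, 2, 3])
for name, value in scores.items():
    print(f"JS {name}: {value:.3f}")
```

Output:

```
sigma = 21.26, iterations = 9, converged = True
centers: [ 55.3 105.  144.8]
JS class_1: 0.978
JS class_2: 0.984
JS class_3: 0.989
JS average: 0.984
```

The phantom is a brain-slice caricature (WM core, cortical GM shell, thin
sulcal/subarachnoid CSF plus a ventricle; class means 50/105/145) corrupted
with 10% Rician noise. The estimated kernel width is 21.3 intensity units;
the converged centers land on the true tissue means, and each tissue
overlaps the ground truth with a Jaccard similarity ≥ 0.978 — plain
`fcm_segment` reaches only ≈ 0.85 average on the same images.

## Command line

```sh
arkfcm phantom  --geometry slice_like --noise-model rician --noise-level 10 --out run/
arkfcm segment  run/phantom_image.png --variant median --out run/
arkfcm evaluate run/phantom_image_labels.png run/phantom_truth.png \
                --image run/phantom_image.png
```

`segment` accepts NIfTI (`.nii`/`.nii.gz`) volumes/slices or grayscale
PNG/TIFF, an optional `--mask`, and writes an integer label map
(0 = background, 1..c = tissues by ascending center — for T1 contrast:
1 = CSF, 2 = GM, 3 = WM) plus a JSON run report with the σ used, iteration
count and objective trace.

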