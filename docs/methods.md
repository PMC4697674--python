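# Methods

## Problem and model

The package segments scalar (single-channel) grayscale images — typically
T1-weighted brain MR slices — into c tissue classes by fuzzy clustering of
intensities, made robust to noise and smooth intensity nonuniformity by an
adaptive spatial regularizer and a kernel-induced distance.

The objective minimized is

    J(u, v) = Σ_i Σ_j u_ij^m [ 2(1 − K(x_i, v_j)) + φ_i · 2(1 − K(x̄_i, v_j)) ],

over foreground pixels i and clusters j, subject to Σ_j u_ij = 1, where
2(1 − K) is the squared distance induced in the GRBF feature space by
K(a,b) = exp(−(a−b)²/2σ²), x̄ is a locally smoothed grayscale and φ the
per-pixel regularization weight. Alternate optimization applies the
fixed-point center update

    v_j ← Σ_i u_ij^m [K(x_i,v_j) x_i + φ_i K(x̄_i,v_j) x̄_i]
          / Σ_i u_ij^m [K(x_i,v_j) + φ_i K(x̄_i,v_j)]

(evaluated at the previous centers, one pass per outer iteration) followed
by the closed-form membership update

    u_ij ∝ [ (1 − K(x_i,v_j)) + φ_i (1 − K(x̄_i,v_j)) ]^{−1/(m−1)},

normalized per pixel. Note the objective carries the *same* factor 2 on
both terms: that is the functional these updates are the exact alternate
minimizers of (the common factor cancels in both), and it is what makes the
recorded objective trace non-increasing. The membership step is an exact
constrained minimizer; the center step is a one-pass Picard iteration of
its stationarity condition, so monotonicity of the full iteration is
asserted empirically by the test suite rather than proven.

Stopping: max_ij |u_ij^(t+1) − u_ij^(t)| < ε (Chebyshev norm over the whole
membership matrix), or the iteration cap; runs hitting the cap are flagged
`converged=False`.

## The adaptive regularizer

For each pixel, over a square window N_i of edge `window_edge` (cardinality
N_R, center included):

1. LVC_i = Σ_{k∈N_i} (x_k − x̄_i)² / (N_R x̄_i²) — window variance
   normalized by the squared window mean. Scale-free (invariant under
   x → a·x). Defined as 0 where the mean is 0; for non-negative images a
   zero mean implies an all-zero window, so this is exact.
2. ζ_i = exp(Σ_{k∈N_i, k≠i} LVC_k); ω_i = ζ_i / Σ_{k∈N_i} ζ_k. The
   exponent sum is unbounded, so ω is computed as a window softmax with the
   window maximum subtracted before exponentiation — mathematically
   identical, overflow-free by construction. Underflow of non-maximal
   entries to exactly 0 is accepted (they are 0 to double precision).
3. φ_i = 2 + ω_i where the pixel is brighter than its window mean, 2 − ω_i
   where darker, 0 where equal. Equality is decided with a 1e−12 relative
   tolerance so that windows that are constant up to floating-point
   summation error yield φ = 0 exactly, keeping the homogeneous-region
   contract (no smoothing there). The base constant 2 is fixed.

The smoothed image x̄ fed to the second objective term is, by variant:
the 3×3 mean filter (ARKFCM₁), the 3×3 median filter (ARKFCM₂), or the
weighted image

    ξ̄_i = [x_i + (1 + max φ)/(N_R − 1) · Σ_{r∈N_i, r≠i} x_r] / (2 + max φ)

(ARKFCM_w), with max φ the global maximum over the foreground. The two
coefficients sum to 1, so ξ̄ is a convex blend of the pixel and its
neighbor mean and never leaves the input range. The neighbor sum excludes
the center (the N_R − 1 divisor implies neighbors only); a center-inclusive
reading would change ξ̄ only slightly and is not implemented. φ itself is
always derived from the arithmetic window mean, independent of the variant;
the variant only changes the smoothed image in the second objective term.
`variant="none"` forces φ ≡ 0, reducing the engine to kernel FCM — used as
the oracle-equivalence hook in the tests.

Windows use replicate (nearest-edge) padding everywhere, so N_R is constant
including at borders; mirror padding would change values only in the
border band. Masked (background) pixels are excluded from clustering and
from σ estimation but still appear as neighbors inside windows of
foreground pixels. 3-D inputs use cubic windows (27 neighbors at edge 3);
2-D is the tested default.

## Kernel width

σ is the sample standard deviation of the distances d_i = |x_i − x̄| of
every foreground grayscale to the global foreground mean,
σ = sqrt(Σ(d_i − d̄)²/(N−1)), estimated once from the *original* image and
shared by both objective terms. It is homogeneous of degree one in the
intensities, which makes the kernel distance invariant under affine
intensity rescaling of the image. A constant image has σ = 0 and raises a
degenerate-input error directing the caller to fixed-σ mode
(`KernelConfig(mode="fixed", sigma=...)`, e.g. the σ = 150 convention of
older kernel-FCM work).

## Parameters

| parameter | default | units | notes |
|---|---|---|---|
| n_clusters c | 3 | — | CSF/GM/WM; use 4 to give background its own cluster |
| fuzzifier m | 2 | — | softness exponent, > 1 |
| ε | 0.001 | membership | Chebyshev threshold on Δu |
| max_iter | 100 | iterations | cap inclusive |
| window_edge | 3 | pixels | 5×5 barely changes bulk accuracy; ≥7×7 erodes thin structures (CSF) — measured by the window-size test |
| σ | data-driven | intensity | see above |
| variant | weighted | — | average / median / weighted / none |

Initialization (`init="percentile_centers"`, deterministic default) places
the c starting centers evenly between the 1st and 99th percentile of the
foreground grayscales. Spreading over *intensity* rather than probability
mass is deliberate: a minority tissue (thin CSF) carries little mass, and
the kernel updates — whose pull decays exponentially with distance — cannot
recover a center initialized far from a small dark mode, while Euclidean
FCM can. `init="random_membership"` (seeded uniform rows, centers from the
fuzzifier-weighted mean) supports randomized-initialization studies; after
the final ascending-center relabeling, different random seeds converge to
identical labelings on well-separated data.

Degenerate cases: a pixel at zero dissimilarity to some center gets a crisp
membership split equally among the tied centers; an empty cluster
(vanishing center denominator) is re-seeded at the grayscale of the pixel
with the lowest maximal membership and logged; argmax label ties break
toward the darker center.

## Metrics

Jaccard similarity is intersection-over-union per class, 1 if the class is
empty in both maps and 0 if empty in exactly one; the unweighted class
average is reported alongside. The entropy measure
E = Σ_j (S_j/S_I) H(R_j) − Σ_j (S_j/S_I) log(S_j/S_I) combines expected
within-region grayscale entropy with layout entropy; background is
excluded. Natural log is the default (base selectable; comparisons are
base-consistent). Integer-valued images use exact intensity bins; float
images a 256-bin histogram over the evaluated range.

## Synthetic phantoms

`generate_phantom` produces piecewise-constant multi-tissue images with
ground truth. Geometries: `concentric` (nested disks, bulky regions,
adjacent regions have adjacent intensities — the clean test bed for exact
recovery), `voronoi` (seeded nearest-point partition, straight boundaries),
and `slice_like` — a brain-slice caricature with a WM core, cortical GM
shell, ~2 px sulcal CSF ribbon inside the GM band, a central ventricle, and
a ~2 px subarachnoid CSF rim so cortex never directly abuts background air
(as in real anatomy). Default 3-class means are 50/105/145 on an 8-bit-like
scale, emulating T1 contrast where the GM/WM separation is much smaller
than CSF/GM.

Corruption: "p% noise" means a noise standard deviation of p% of the
brightest class mean (the convention of simulated-brain-database noise
levels). Gaussian noise is additive; Rician noise is
sqrt((x+n₁)² + n₂²) with independent zero-mean Gaussians n₁, n₂;
salt-and-pepper sets p% of pixels to the global min/max. The bias field
multiplies by 1 + A·B with B a smooth separable cosine surface in [−1, 1]
(A = 0.2 for "20% nonuniformity"); the bias is applied before noise and
the result clamped at 0, matching magnitude images.

What the phantoms do **not** emulate: partial-volume voxels, tissue
texture, MR contrast physics, and anatomical variability. Consequences are
visible in the validation: on sharp piecewise-constant boundaries plain FCM
is nearly noise-free-optimal at 7% Gaussian noise (every boundary pixel is
unambiguous in intensity), so the mean-filter and weighted-image variants —
which pay an edge-blurring cost at CSF/WM junctions where the blurred value
resembles GM — can score *below* FCM there, while the edge-preserving
median variant scores above it. Under the heavier 10% Rician regime, and on
bulky-region phantoms at 7% Gaussian noise, all three regularized variants
clearly beat FCM. Passing these tests demonstrates correctness of the
machinery and the expected robustness ordering under heavy noise; it does
not by itself predict accuracy on real MR data, where partial volume makes
intensity-only clustering much weaker.

## Problem sizes

The test suite and the reproduction script use 128×128 slice-like phantoms
(10 paired seeds per corruption regime), 64×64/48×48 phantoms for exact
recovery, 32×32 images for oracle-equivalence and convergence checks, and
16×16 images for brute-force field equivalence — sizes at which every
brute-force reference (pure-Python nested loops) remains exact and fast
while exercising the identical code paths used at full slice resolution.

## Known limitations

* Severe noise in 1–2 px wide structures between edges can still be
  mislabeled; larger windows make this strictly worse (hence the 3×3
  default).
* The method does not model or correct the bias field; it only tolerates
  it. Strong nonuniformity that overlaps class intensity ranges across the
  image will degrade any intensity-based clustering, this one included.
* The center update is a one-pass fixed point; the objective decrease per
  iteration is checked empirically, not guaranteed.
* Multi-channel inputs, registration, skull stripping and bias-field
  correction are out of scope.
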