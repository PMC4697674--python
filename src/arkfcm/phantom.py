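"""Synthetic piecewise-constant phantoms with MR-like corruption.

The generator produces multi-tissue test images with known ground truth so
the whole segmentation pipeline can be validated without external brain
databases.  Three geometries are available:

* ``concentric`` — nested disks partitioning the full image (no background);
* ``voronoi`` — a seeded nearest-point partition with straight boundaries;
* ``slice_like`` — a brain-slice caricature: a smooth cortical blob
  containing a white-matter core wrapped in a thin (~2 px) dark ribbon plus
  a small central ventricle, mimicking the thin-CSF structures that spatial
  regularization tends to erode.  Labels: 1 = CSF analog (darkest),
  2 = GM analog, 3 = WM analog (brightest); everything outside the blob is
  background (label 0).

Corruption follows MR simulation conventions: a noise level of p% means a
noise standard deviation of p% of the brightest class mean (additive
Gaussian, or the two Gaussian components of Rician magnitude noise);
salt-and-pepper sets p% of pixels to the global min/max; the bias field is
a smooth multiplicative shading ``1 + amplitude * B`` with B in [-1, 1].
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence, Tuple

import numpy as np

from .image import GrayImage

__all__ = ["PhantomSpec", "Phantom", "generate_phantom", "corrupt_image"]

GEOMETRIES = ("concentric", "voronoi", "slice_like")
NOISE_MODELS = ("gaussian", "salt_pepper", "rician", "none")


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Phantom recipe; regenerating with the same spec is bit-identical."""

    shape: Tuple[int, ...] = (128, 128)
    n_classes: int = 3
    class_means: Optional[Tuple[float, ...]] = None
    geometry: str = "slice_like"
    noise_model: str = "none"
    noise_level: float = 0.0
    bias_field: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.geometry not in GEOMETRIES:
            raise ValueError(f"geometry must be one of {GEOMETRIES}")
        if self.noise_model not in NOISE_MODELS:
            raise ValueError(f"noise_model must be one of {NOISE_MODELS}")
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")
        if self.bias_field < 0:
            raise ValueError("bias_field amplitude must be >= 0")
        if self.geometry == "slice_like" and self.n_classes != 3:
            raise ValueError("slice_like geometry models exactly 3 tissue classes")
        if len(self.shape) != 2:
            raise ValueError("phantom generation is 2-D")
        if self.class_means is not None:
            means = tuple(float(v) for v in self.class_means)
            if len(means) != self.n_classes:
                raise ValueError("class_means length must equal n_classes")
            if len(set(means)) != len(means):
                raise ValueError("class_means must be pairwise distinct")
            object.__setattr__(self, "class_means", means)

    def resolved_means(self) -> np.ndarray:
        if self.class_means is not None:
            return np.asarray(self.class_means, dtype=np.float64)
        if self.n_classes == 3:
            # T1-weighted contrast on an 8-bit scale: CSF dark, GM mid,
            # WM bright, with the GM/WM separation much smaller than the
            # CSF/GM one — as in simulated T1 brain volumes.
            return np.array([50.0, 105.0, 145.0])
        return np.linspace(60.0, 240.0, self.n_classes)


@dataclasses.dataclass
class Phantom:
    image: GrayImage
    truth: np.ndarray
    spec: PhantomSpec


def _labels_concentric(spec: PhantomSpec) -> np.ndarray:
    ny, nx = spec.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    r = np.hypot(yy - (ny - 1) / 2.0, xx - (nx - 1) / 2.0)
    r_max = 0.48 * min(ny, nx)
    # Nested disks: innermost disk = highest label, outside all = label 1.
    radii = r_max * np.sqrt(np.arange(spec.n_classes - 1, 0, -1) / spec.n_classes)
    labels = np.ones(spec.shape, dtype=np.int32)
    for k, rad in enumerate(radii):
        labels[r <= rad] = k + 2
    return labels


def _labels_voronoi(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    ny, nx = spec.shape
    pts = rng.uniform(low=[0.15 * ny, 0.15 * nx], high=[0.85 * ny, 0.85 * nx],
                      size=(spec.n_classes, 2))
    yy, xx = np.mgrid[0:ny, 0:nx]
    d2 = (yy[..., None] - pts[:, 0]) ** 2 + (xx[..., None] - pts[:, 1]) ** 2
    return (np.argmin(d2, axis=-1) + 1).astype(np.int32)


def _labels_slice_like(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    ny, nx = spec.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    dy, dx = yy - cy, xx - cx
    r = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    scale = min(ny, nx)

    phases = rng.uniform(0.0, 2.0 * np.pi, size=4)
    wobble = (
        1.0
        + 0.10 * np.cos(2 * theta + phases[0])
        + 0.06 * np.cos(3 * theta + phases[1])
        + 0.03 * np.cos(5 * theta + phases[2])
    )
    r_outer = 0.42 * scale * wobble
    wobble_wm = 1.0 + 0.08 * np.cos(3 * theta + phases[3]) + 0.05 * np.cos(
        2 * theta + phases[0]
    )
    r_wm = 0.62 * 0.42 * scale * wobble_wm
    ribbon = 2.0  # thin sulcal-CSF ribbon width in pixels

    labels = np.zeros(spec.shape, dtype=np.int32)
    inside = r <= r_outer
    # Subarachnoid CSF: the cortical surface is bathed in CSF, so the
    # outermost foreground layer is dark rather than abutting air directly.
    labels[inside] = 1
    labels[inside & (r <= r_outer - ribbon)] = 2  # cortical GM shell
    labels[inside & (r <= r_wm)] = 3  # WM core
    # Sulcal CSF: a thin ribbon embedded mid-shell in the GM band, so it is
    # bounded by GM on both sides as in a real sulcus.
    r_sulcus = 0.5 * (r_wm + r_outer)
    labels[inside & (r > r_sulcus) & (r <= r_sulcus + ribbon)] = 1
    labels[inside & (r <= 0.10 * scale)] = 1  # central ventricle (CSF)
    return labels


def _smooth_bias(shape: Tuple[int, int]) -> np.ndarray:
    """Low-order smooth surface with values in [-1, 1] (bright center)."""
    ny, nx = shape
    u = np.linspace(0.0, 1.0, ny)[:, None]
    w = np.linspace(0.0, 1.0, nx)[None, :]
    bowl = np.cos(np.pi * (u - 0.5)) * np.cos(np.pi * (w - 0.5))
    return 2.0 * bowl - 1.0


def _apply_noise(
    pixels: np.ndarray,
    noise_model: str,
    noise_level: float,
    ref_intensity: float,
    rng: np.random.Generator,
) -> np.ndarray:
    if noise_model == "none" or noise_level == 0.0:
        return pixels.copy()
    std = noise_level / 100.0 * ref_intensity
    if noise_model == "gaussian":
        out = pixels + rng.normal(0.0, std, size=pixels.shape)
    elif noise_model == "rician":
        n1 = rng.normal(0.0, std, size=pixels.shape)
        n2 = rng.normal(0.0, std, size=pixels.shape)
        out = np.sqrt((pixels + n1) ** 2 + n2**2)
    elif noise_model == "salt_pepper":
        out = pixels.copy()
        n_corrupt = int(round(noise_level / 100.0 * pixels.size))
        idx = rng.choice(pixels.size, size=n_corrupt, replace=False)
        vals = np.where(
            rng.uniform(size=n_corrupt) < 0.5, pixels.min(), pixels.max()
        )
        out.flat[idx] = vals
    else:
        raise ValueError(f"unknown noise model {noise_model!r}")
    return np.clip(out, 0.0, None)


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Generate a phantom image, ground-truth labels and foreground mask."""
    rng = np.random.default_rng(spec.seed)
    if spec.geometry == "concentric":
        truth = _labels_concentric(spec)
    elif spec.geometry == "voronoi":
        truth = _labels_voronoi(spec, rng)
    else:
        truth = _labels_slice_like(spec, rng)

    present = np.unique(truth[truth > 0])
    if present.size != spec.n_classes:
        raise ValueError(
            f"degenerate geometry: only classes {present.tolist()} generated"
        )

    means = spec.resolved_means()
    pixels = np.zeros(spec.shape, dtype=np.float64)
    for c in range(1, spec.n_classes + 1):
        pixels[truth == c] = means[c - 1]

    if spec.bias_field > 0.0:
        pixels = pixels * (1.0 + spec.bias_field * _smooth_bias(spec.shape))
        pixels = np.clip(pixels, 0.0, None)

    pixels = _apply_noise(
        pixels, spec.noise_model, spec.noise_level, float(means.max()), rng
    )
    mask = truth > 0
    image = GrayImage(pixels=pixels, mask=None if mask.all() else mask)
    return Phantom(image=image, truth=truth, spec=spec)


def corrupt_image(
    img: GrayImage, noise_model: str, noise_level: float, seed: int
) -> GrayImage:
    """Apply the phantom noise contracts to an arbitrary image."""
    if noise_model not in NOISE_MODELS:
        raise ValueError(f"noise_model must be one of {NOISE_MODELS}")
    rng = np.random.default_rng(seed)
    ref = float(img.pixels.max())
    out = _apply_noise(img.pixels, noise_model, noise_level, ref, rng)
    return GrayImage(pixels=out, mask=img.mask, spacing=img.spacing)
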