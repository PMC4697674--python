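"""Grayscale image container and local window filtering.

The clustering engine operates on scalar (single-channel) images in two or
three dimensions.  All neighborhood operations use a square (cubic in 3-D)
window of odd edge length centered on each pixel; image borders are handled
by replicate (nearest-edge) padding so the window cardinality ``N_R`` is the
same at every pixel.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "GrayImage",
    "NeighborhoodSpec",
    "neighborhoods",
    "local_mean",
    "local_median",
]


class ConfigurationError(ValueError):
    """Raised for invalid algorithm configuration (e.g. window larger than image)."""


@dataclasses.dataclass(frozen=True)
class NeighborhoodSpec:
    """Square/cubic local window specification.

    Parameters
    ----------
    window_edge:
        Odd edge length of the window in pixels (default 3, i.e. a 3x3
        window in 2-D with cardinality ``N_R = 9``).
    boundary_policy:
        How windows that overhang the image border are filled.  Only
        ``"replicate"`` (nearest-edge padding) is supported; it keeps the
        window cardinality constant everywhere.
    """

    window_edge: int = 3
    boundary_policy: str = "replicate"

    def __post_init__(self) -> None:
        if not isinstance(self.window_edge, (int, np.integer)):
            raise ConfigurationError("window_edge must be an integer")
        if self.window_edge < 3 or self.window_edge % 2 == 0:
            raise ConfigurationError(
                f"window_edge must be an odd integer >= 3, got {self.window_edge}"
            )
        if self.boundary_policy != "replicate":
            raise ConfigurationError(
                f"unsupported boundary_policy {self.boundary_policy!r}"
            )

    def cardinality(self, ndim: int) -> int:
        """Window cardinality N_R = window_edge ** ndim."""
        return int(self.window_edge**ndim)


@dataclasses.dataclass
class GrayImage:
    """A scalar grayscale image with an optional foreground mask.

    Attributes
    ----------
    pixels:
        2-D or 3-D array of finite grayscales (native intensity units; no
        normalization is forced).
    mask:
        Optional boolean array of the same shape; True marks foreground
        pixels that participate in clustering.  Background pixels are
        excluded from clustering and from kernel-width estimation but still
        contribute as neighbors inside local windows.
    spacing:
        Optional per-axis physical voxel size.  Ignored by the algorithm,
        preserved on output.
    """

    pixels: np.ndarray
    mask: Optional[np.ndarray] = None
    spacing: Optional[Tuple[float, ...]] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim not in (2, 3):
            raise ValueError(f"pixels must be 2-D or 3-D, got ndim={px.ndim}")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixels contain NaN or Inf")
        self.pixels = px
        if self.mask is not None:
            m = np.asarray(self.mask, dtype=bool)
            if m.shape != px.shape:
                raise ValueError(
                    f"mask shape {m.shape} differs from pixels shape {px.shape}"
                )
            if not m.any():
                raise ValueError("mask has no foreground pixels")
            self.mask = m

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.pixels.shape

    @property
    def ndim(self) -> int:
        return self.pixels.ndim

    def foreground(self) -> np.ndarray:
        """Boolean foreground mask (all-True when no mask was given)."""
        if self.mask is None:
            return np.ones(self.pixels.shape, dtype=bool)
        return self.mask

    def foreground_values(self) -> np.ndarray:
        """1-D array of foreground grayscales."""
        return self.pixels[self.foreground()]


def _check_window(img: GrayImage, spec: NeighborhoodSpec) -> None:
    if any(spec.window_edge > s for s in img.shape):
        raise ConfigurationError(
            f"window edge {spec.window_edge} exceeds image shape {img.shape}"
        )


def neighborhoods(arr: np.ndarray, spec: NeighborhoodSpec) -> np.ndarray:
    """Return all local windows of ``arr`` as a trailing axis.

    Output has shape ``arr.shape + (N_R,)``; the window elements are in
    row-major order, so the center pixel sits at index ``N_R // 2``.
    Borders use replicate padding.
    """
    pad = spec.window_edge // 2
    padded = np.pad(arr, pad, mode="edge")
    win = sliding_window_view(padded, (spec.window_edge,) * arr.ndim)
    return win.reshape(arr.shape + (-1,))


def local_mean(img: GrayImage, spec: NeighborhoodSpec) -> np.ndarray:
    """Arithmetic mean of the window centered at each pixel (center included)."""
    _check_window(img, spec)
    return neighborhoods(img.pixels, spec).mean(axis=-1)


def local_median(img: GrayImage, spec: NeighborhoodSpec) -> np.ndarray:
    """Median of the window centered at each pixel (center included)."""
    _check_window(img, spec)
    return np.median(neighborhoods(img.pixels, spec), axis=-1)
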