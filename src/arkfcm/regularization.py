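"""Adaptive spatial regularization for kernel fuzzy clustering.

The regularizer assigns every pixel a weight ``phi`` that controls how
strongly the locally smoothed image influences its clustering:

* the local variation coefficient (LVC) measures grayscale heterogeneity
  inside the window, normalized by the squared local mean so it is
  invariant to rescaling the image by a positive constant;
* the LVC values of the *neighbors* of each pixel are summed and passed
  through an exponential, then normalized over the window (a softmax),
  giving a weight ``omega`` in [0, 1];
* ``phi`` is ``2 + omega`` where the pixel is brighter than its local mean,
  ``2 - omega`` where it is darker, and 0 where the two coincide, so that
  homogeneous regions receive no spatial smoothing at all.

A weighted image ``xi`` blends each pixel with its neighborhood mean using
the global maximum of ``phi``; it is the smoothing input of the
ARKFCM_w variant.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .image import GrayImage, NeighborhoodSpec, _check_window, neighborhoods

__all__ = [
    "RegularizerField",
    "WeightedImage",
    "compute_lvc",
    "compute_phi",
    "weighted_image",
]

# Relative tolerance for deciding that the local mean equals the center
# grayscale (the phi = 0 branch).  Window means of exactly constant
# neighborhoods can differ from the center by a few ulps after floating
# summation; this tolerance absorbs that without affecting genuine
# inhomogeneity.
_EQ_RTOL = 1e-12


@dataclasses.dataclass
class RegularizerField:
    """Per-pixel regularization weights and their intermediates.

    ``phi`` takes values in {0} | (2 - omega, 2 + omega) pointwise and is
    bounded by [0, 3] since omega <= 1.
    """

    lvc: np.ndarray
    omega: np.ndarray
    phi: np.ndarray
    base_constant: float = 2.0


@dataclasses.dataclass
class WeightedImage:
    """The phi-weighted blend of each pixel with its neighborhood mean."""

    values: np.ndarray
    phi_max: float


def compute_lvc(img: GrayImage, spec: NeighborhoodSpec) -> np.ndarray:
    """Local variation coefficient: window variance over squared window mean.

    ``LVC_i = sum_{k in N_i} (x_k - xbar_i)^2 / (N_R * xbar_i^2)``, defined
    as 0 where the window mean is 0.  For non-negative images a zero mean
    implies an all-zero window, so the convention is exact; if negative
    grayscales produced a zero mean with nonzero variance the denominator is
    clamped and a warning is emitted.
    """
    _check_window(img, spec)
    win = neighborhoods(img.pixels, spec)
    n_r = spec.cardinality(img.ndim)
    xbar = win.mean(axis=-1)
    ssq = ((win - xbar[..., None]) ** 2).sum(axis=-1)
    zero_mean = xbar == 0.0
    if np.any(zero_mean & (ssq > 0.0)):
        warnings.warn(
            "zero window mean with nonzero variance (negative grayscales?); "
            "LVC denominator clamped",
            RuntimeWarning,
            stacklevel=2,
        )
    denom = np.where(zero_mean, 1.0, n_r * xbar**2)
    lvc = np.where(zero_mean & (ssq == 0.0), 0.0, ssq / denom)
    return lvc


def compute_phi(
    img: GrayImage, lvc: np.ndarray, spec: NeighborhoodSpec
) -> RegularizerField:
    """Turn the LVC field into the adaptive per-pixel weight ``phi``.

    ``zeta_i = exp(sum_{k in N_i, k != i} LVC_k)`` and
    ``omega_i = zeta_i / sum_{k in N_i} zeta_k``.  Because the exponent sums
    are unbounded, omega is evaluated as a window softmax with the window
    maximum subtracted before exponentiation — mathematically identical,
    immune to overflow.
    """
    if lvc.shape != img.shape:
        raise ValueError("lvc shape does not match image shape")
    _check_window(img, spec)

    # Neighbor-only LVC sum: full window sum minus the center's own LVC.
    lvc_win = neighborhoods(lvc, spec)
    s = lvc_win.sum(axis=-1) - lvc

    # omega_i is a softmax of s over the window of i (center value picked out).
    s_win = neighborhoods(s, spec)
    s_max = s_win.max(axis=-1)
    omega = np.exp(s - s_max) / np.exp(s_win - s_max[..., None]).sum(axis=-1)

    xbar = neighborhoods(img.pixels, spec).mean(axis=-1)
    diff = img.pixels - xbar
    tol = _EQ_RTOL * np.maximum(np.abs(img.pixels), np.abs(xbar))
    equal = np.abs(diff) <= tol
    phi = np.where(equal, 0.0, np.where(diff > 0.0, 2.0 + omega, 2.0 - omega))
    return RegularizerField(lvc=lvc, omega=omega, phi=phi)


def weighted_image(
    img: GrayImage, reg: RegularizerField, spec: NeighborhoodSpec
) -> WeightedImage:
    """Blend each pixel with its neighborhood mean, weighted by max(phi).

    ``xi_i = [x_i + (1 + max_phi)/(N_R - 1) * sum_{r in N_i, r != i} x_r]
    / (2 + max_phi)`` with ``max_phi`` the global maximum of phi over the
    foreground.  The coefficients of the center and the neighbor mean sum to
    1, so the output never leaves the input intensity range.
    """
    _check_window(img, spec)
    n_r = spec.cardinality(img.ndim)
    phi_max = float(reg.phi[img.foreground()].max())
    neighbor_sum = neighborhoods(img.pixels, spec).sum(axis=-1) - img.pixels
    values = (img.pixels + (1.0 + phi_max) / (n_r - 1) * neighbor_sum) / (
        2.0 + phi_max
    )
    return WeightedImage(values=values, phi_max=phi_max)
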