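"""ARKFCM clustering engine and the plain FCM baseline.

The adaptively regularized kernel fuzzy C-means objective is

    J = sum_i sum_j u_ij^m ( ||Phi(x_i) - Phi(v_j)||^2
                             + phi_i ||Phi(xbar_i) - Phi(v_j)||^2 ),

with the kernel-induced squared distance ||Phi(a) - Phi(b)||^2
= 2 (1 - K(a, b)), summed over foreground pixels, where ``x`` is the original grayscale,
``xbar`` a locally smoothed grayscale (mean, median, or the phi-weighted
image, giving the three variants ARKFCM_1 / ARKFCM_2 / ARKFCM_w), ``phi``
the adaptive regularization weight and ``K`` the GRBF kernel.  It is
minimized by alternate optimization: a fixed-point center update followed by
the closed-form membership update, until the Chebyshev norm of the
membership change drops below ``epsilon`` or the iteration cap is hit.

With ``variant="none"`` phi is forced to zero and the engine reduces to
kernel FCM on raw grayscales; ``fcm_segment`` is the classical
Euclidean-distance FCM, kept as a baseline.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import List

import numpy as np

from .image import ConfigurationError, GrayImage, NeighborhoodSpec, local_mean, local_median
from .kernel import KernelConfig, grbf, resolve_sigma
from .regularization import compute_lvc, compute_phi, weighted_image

__all__ = [
    "ClusterConfig",
    "FuzzyPartition",
    "SegmentationResult",
    "arkfcm_objective",
    "update_memberships",
    "update_centers",
    "arkfcm_segment",
    "fcm_segment",
]

logger = logging.getLogger(__name__)

VARIANTS = ("average", "median", "weighted", "none")


@dataclasses.dataclass(frozen=True)
class ClusterConfig:
    """Clustering hyperparameters.

    Defaults follow the standard operating point of the method: fuzzifier
    m = 2, convergence threshold epsilon = 0.001 on the maximum membership
    change, and an iteration cap of 100.
    """

    n_clusters: int = 3
    m: float = 2.0
    epsilon: float = 1e-3
    max_iter: int = 100
    variant: str = "weighted"
    seed: int = 0
    init: str = "percentile_centers"

    def __post_init__(self) -> None:
        if self.n_clusters < 2:
            raise ConfigurationError("n_clusters must be >= 2")
        if self.m <= 1:
            raise ConfigurationError("fuzzifier m must be > 1")
        if self.epsilon <= 0:
            raise ConfigurationError("epsilon must be positive")
        if self.max_iter < 1:
            raise ConfigurationError("max_iter must be positive")
        if self.variant not in VARIANTS:
            raise ConfigurationError(
                f"variant must be one of {VARIANTS}, got {self.variant!r}"
            )
        if self.init not in ("percentile_centers", "random_membership"):
            raise ConfigurationError(f"unknown init {self.init!r}")


@dataclasses.dataclass
class FuzzyPartition:
    """Membership matrix (foreground pixels x clusters) and cluster centers."""

    memberships: np.ndarray
    centers: np.ndarray


@dataclasses.dataclass
class SegmentationResult:
    """Converged segmentation.

    ``labels`` is 0 on background and 1..c on the foreground, with labels
    numbered by ascending cluster center (1 = darkest tissue).
    """

    labels: np.ndarray
    partition: FuzzyPartition
    objective_trace: List[float]
    n_iter: int
    converged: bool
    sigma: float
    variant: str


def arkfcm_objective(
    x: np.ndarray,
    xbar: np.ndarray,
    phi: np.ndarray,
    memberships: np.ndarray,
    centers: np.ndarray,
    m: float,
    sigma: float,
) -> float:
    """Evaluate the ARKFCM objective over foreground pixels (1-D arrays).

    Both the data term and the regularization term are kernel-induced
    squared distances ``||Phi(.) - Phi(v)||^2 = 2 (1 - K)``:

        J = sum_i sum_j u_ij^m [2 (1 - K(x_i, v_j))
                                 + phi_i * 2 (1 - K(xbar_i, v_j))].

    This is the functional whose exact alternate-optimization updates are
    ``update_memberships`` and ``update_centers`` (the shared factor 2
    cancels in both).
    """
    um = memberships**m
    k_x = grbf(x[:, None], centers[None, :], sigma)
    k_xb = grbf(xbar[:, None], centers[None, :], sigma)
    j = 2.0 * (um * (1.0 - k_x)).sum() + 2.0 * (phi[:, None] * um * (1.0 - k_xb)).sum()
    return float(j)


def _dissimilarity(
    x: np.ndarray, xbar: np.ndarray, phi: np.ndarray, centers: np.ndarray, sigma: float
) -> np.ndarray:
    """Per pixel/cluster dissimilarity (1-K(x,v)) + phi (1-K(xbar,v))."""
    k_x = grbf(x[:, None], centers[None, :], sigma)
    k_xb = grbf(xbar[:, None], centers[None, :], sigma)
    return (1.0 - k_x) + phi[:, None] * (1.0 - k_xb)


def update_memberships(
    x: np.ndarray,
    xbar: np.ndarray,
    phi: np.ndarray,
    centers: np.ndarray,
    m: float,
    sigma: float,
) -> np.ndarray:
    """Closed-form membership update; rows sum to 1.

    Pixels whose dissimilarity to some center is exactly zero get a crisp
    assignment split equally among the tied zero-dissimilarity clusters
    (the standard FCM singularity convention).
    """
    d = _dissimilarity(x, xbar, phi, centers, sigma)
    u = np.empty_like(d)
    zero = d <= 0.0
    singular = zero.any(axis=1)
    if singular.any():
        z = zero[singular]
        u[singular] = z / z.sum(axis=1, keepdims=True)
    regular = ~singular
    if regular.any():
        dr = d[regular]
        # u_ij = 1 / sum_k (d_ij / d_ik)^{1/(m-1)}; ratio form avoids
        # overflow when some d is tiny.
        ratio = (dr[:, :, None] / dr[:, None, :]) ** (1.0 / (m - 1.0))
        u[regular] = 1.0 / ratio.sum(axis=2)
    return u


def update_centers(
    x: np.ndarray,
    xbar: np.ndarray,
    phi: np.ndarray,
    memberships: np.ndarray,
    centers: np.ndarray,
    m: float,
    sigma: float,
) -> np.ndarray:
    """Fixed-point center update, evaluated at the previous centers.

    Each new center is a convex combination of the x_i and xbar_i, hence
    stays inside the data range.  A cluster whose denominator vanishes
    (empty cluster) is re-seeded at the grayscale of the pixel with the
    lowest maximal membership.
    """
    um = memberships**m
    k_x = grbf(x[:, None], centers[None, :], sigma)
    k_xb = grbf(xbar[:, None], centers[None, :], sigma)
    w = phi[:, None] * k_xb
    num = (um * (k_x * x[:, None] + w * xbar[:, None])).sum(axis=0)
    den = (um * (k_x + w)).sum(axis=0)
    new = np.empty_like(centers)
    ok = den > np.finfo(np.float64).tiny
    new[ok] = num[ok] / den[ok]
    if not ok.all():
        worst = int(np.argmin(memberships.max(axis=1)))
        new[~ok] = x[worst]
        logger.warning(
            "empty cluster(s) %s re-seeded at pixel grayscale %g",
            np.nonzero(~ok)[0].tolist(),
            x[worst],
        )
    return new


def _percentile_centers(x: np.ndarray, c: int) -> np.ndarray:
    """Deterministic initial centers: even spread over the robust range.

    Centers are placed evenly between the 1st and 99th grayscale
    percentiles.  Spreading over intensity (rather than probability mass)
    keeps an initial center near every tissue mode even when one tissue
    occupies few pixels — important for the kernel updates, whose pull
    decays exponentially with distance.
    """
    lo, hi = np.percentile(x, [1.0, 99.0])
    if hi <= lo:
        lo, hi = float(x.min()), float(x.max())
    centers = np.linspace(lo, hi, c)
    if np.unique(centers).size < c:
        raise ConfigurationError("degenerate grayscale range for initialization")
    return centers


def _initial_state(
    x: np.ndarray, phi: np.ndarray, xbar: np.ndarray, cfg: ClusterConfig, sigma: float
) -> tuple[np.ndarray, np.ndarray]:
    """Initial centers and memberships.

    ``percentile_centers`` (deterministic default): centers evenly spread
    over the robust grayscale range, memberships from one membership
    update.  ``random_membership``: seeded uniform rows normalized to sum to
    1, centers from the fuzzifier-weighted grayscale mean.
    """
    c = cfg.n_clusters
    if cfg.init == "percentile_centers":
        centers = _percentile_centers(x, c)
        u = update_memberships(x, xbar, phi, centers, cfg.m, sigma)
    else:
        rng = np.random.default_rng(cfg.seed)
        u = rng.uniform(size=(x.size, c))
        u /= u.sum(axis=1, keepdims=True)
        um = u**cfg.m
        centers = (um * x[:, None]).sum(axis=0) / um.sum(axis=0)
    return centers, u


def _relabel_ascending(
    u: np.ndarray, centers: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    order = np.argsort(centers, kind="stable")
    centers_sorted = centers[order]
    u_sorted = u[:, order]
    # argmax on the sorted columns breaks ties toward the darker center
    labels_sorted = np.argmax(u_sorted, axis=1) + 1
    return labels_sorted, u_sorted, centers_sorted


def arkfcm_segment(
    img: GrayImage,
    cfg: ClusterConfig = ClusterConfig(),
    spec: NeighborhoodSpec = NeighborhoodSpec(),
    kernel_cfg: KernelConfig = KernelConfig(),
) -> SegmentationResult:
    """Segment ``img`` with the requested ARKFCM variant.

    Pipeline: compute phi once from the local means; build the smoothing
    image for the variant (average filter, median filter, or the weighted
    image; ``variant="none"`` disables regularization entirely); estimate
    sigma from the original foreground grayscales; alternate center and
    membership updates until ``max |u(t+1) - u(t)| < epsilon`` or the
    iteration cap.
    """
    fg = img.foreground()
    n_fg = int(fg.sum())
    if cfg.n_clusters >= n_fg:
        raise ConfigurationError(
            f"n_clusters={cfg.n_clusters} must be < number of foreground pixels {n_fg}"
        )
    sigma = resolve_sigma(img, kernel_cfg)

    if cfg.variant == "none":
        phi_field = np.zeros(img.shape)
        smooth = img.pixels
    else:
        reg = compute_phi(img, compute_lvc(img, spec), spec)
        phi_field = reg.phi
        if cfg.variant == "average":
            smooth = local_mean(img, spec)
        elif cfg.variant == "median":
            smooth = local_median(img, spec)
        else:  # weighted
            smooth = weighted_image(img, reg, spec).values

    x = img.pixels[fg]
    xbar = smooth[fg]
    phi = phi_field[fg]

    centers, u = _initial_state(x, phi, xbar, cfg, sigma)
    trace = [arkfcm_objective(x, xbar, phi, u, centers, cfg.m, sigma)]
    converged = False
    n_iter = 0
    for _ in range(cfg.max_iter):
        n_iter += 1
        centers = update_centers(x, xbar, phi, u, centers, cfg.m, sigma)
        u_new = update_memberships(x, xbar, phi, centers, cfg.m, sigma)
        delta = float(np.max(np.abs(u_new - u)))
        u = u_new
        j = arkfcm_objective(x, xbar, phi, u, centers, cfg.m, sigma)
        trace.append(j)
        logger.debug("iter %d: J=%.8g max|du|=%.3g", n_iter, j, delta)
        if delta < cfg.epsilon:
            converged = True
            break

    labels_fg, u_sorted, centers_sorted = _relabel_ascending(u, centers)
    labels = np.zeros(img.shape, dtype=np.int32)
    labels[fg] = labels_fg
    return SegmentationResult(
        labels=labels,
        partition=FuzzyPartition(memberships=u_sorted, centers=centers_sorted),
        objective_trace=trace,
        n_iter=n_iter,
        converged=converged,
        sigma=sigma,
        variant=cfg.variant,
    )


def fcm_segment(img: GrayImage, cfg: ClusterConfig = ClusterConfig()) -> SegmentationResult:
    """Classical fuzzy C-means on grayscales with squared Euclidean distance.

    Shares the initialization, stopping rule and labeling conventions of
    ``arkfcm_segment``; serves as the unregularized baseline.
    """
    fg = img.foreground()
    n_fg = int(fg.sum())
    if cfg.n_clusters >= n_fg:
        raise ConfigurationError(
            f"n_clusters={cfg.n_clusters} must be < number of foreground pixels {n_fg}"
        )
    x = img.pixels[fg]
    c = cfg.n_clusters

    def fcm_memberships(centers: np.ndarray) -> np.ndarray:
        d = (x[:, None] - centers[None, :]) ** 2
        u = np.empty_like(d)
        zero = d <= 0.0
        singular = zero.any(axis=1)
        if singular.any():
            z = zero[singular]
            u[singular] = z / z.sum(axis=1, keepdims=True)
        regular = ~singular
        if regular.any():
            dr = d[regular]
            ratio = (dr[:, :, None] / dr[:, None, :]) ** (1.0 / (cfg.m - 1.0))
            u[regular] = 1.0 / ratio.sum(axis=2)
        return u

    if cfg.init == "percentile_centers":
        centers = _percentile_centers(x, c)
        u = fcm_memberships(centers)
    else:
        rng = np.random.default_rng(cfg.seed)
        u = rng.uniform(size=(x.size, c))
        u /= u.sum(axis=1, keepdims=True)
        um = u**cfg.m
        centers = (um * x[:, None]).sum(axis=0) / um.sum(axis=0)

    def objective(u: np.ndarray, centers: np.ndarray) -> float:
        return float(((u**cfg.m) * (x[:, None] - centers[None, :]) ** 2).sum())

    trace = []
    converged = False
    n_iter = 0
    for _ in range(cfg.max_iter):
        n_iter += 1
        um = u**cfg.m
        den = um.sum(axis=0)
        centers = np.where(
            den > np.finfo(np.float64).tiny, (um * x[:, None]).sum(axis=0) / den, centers
        )
        u_new = fcm_memberships(centers)
        delta = float(np.max(np.abs(u_new - u)))
        u = u_new
        trace.append(objective(u, centers))
        if delta < cfg.epsilon:
            converged = True
            break

    labels_fg, u_sorted, centers_sorted = _relabel_ascending(u, centers)
    labels = np.zeros(img.shape, dtype=np.int32)
    labels[fg] = labels_fg
    return SegmentationResult(
        labels=labels,
        partition=FuzzyPartition(memberships=u_sorted, centers=centers_sorted),
        objective_trace=trace,
        n_iter=n_iter,
        converged=converged,
        sigma=float("nan"),
        variant="fcm",
    )
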