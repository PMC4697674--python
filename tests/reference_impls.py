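"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plain per-pixel Python loops, deliberately
avoiding the vectorized code paths of the package, so agreement between the
two is meaningful.
"""

from __future__ import annotations

import math

import numpy as np

EQ_RTOL = 1e-12  # same local-mean-equals-center convention as production


def _window_coords(i, j, ny, nx, pad):
    for di in range(-pad, pad + 1):
        for dj in range(-pad, pad + 1):
            yield min(max(i + di, 0), ny - 1), min(max(j + dj, 0), nx - 1)


def brute_local_mean(pixels: np.ndarray, edge: int) -> np.ndarray:
    ny, nx = pixels.shape
    pad = edge // 2
    out = np.zeros_like(pixels, dtype=float)
    for i in range(ny):
        for j in range(nx):
            vals = [pixels[p, q] for p, q in _window_coords(i, j, ny, nx, pad)]
            out[i, j] = sum(vals) / len(vals)
    return out


def brute_local_median(pixels: np.ndarray, edge: int) -> np.ndarray:
    ny, nx = pixels.shape
    pad = edge // 2
    out = np.zeros_like(pixels, dtype=float)
    for i in range(ny):
        for j in range(nx):
            vals = sorted(pixels[p, q] for p, q in _window_coords(i, j, ny, nx, pad))
            n = len(vals)
            out[i, j] = vals[n // 2] if n % 2 else 0.5 * (vals[n // 2 - 1] + vals[n // 2])
    return out


def brute_regularizer(pixels: np.ndarray, edge: int):
    """Per-pixel-loop LVC, omega, phi and weighted image (replicate padding).

    Returns (lvc, omega, phi, xi).
    """
    ny, nx = pixels.shape
    pad = edge // 2
    n_r = edge * edge
    xbar = brute_local_mean(pixels, edge)
    lvc = np.zeros_like(pixels, dtype=float)
    for i in range(ny):
        for j in range(nx):
            m = xbar[i, j]
            ss = sum(
                (pixels[p, q] - m) ** 2 for p, q in _window_coords(i, j, ny, nx, pad)
            )
            lvc[i, j] = 0.0 if m == 0.0 else ss / (n_r * m * m)

    # zeta exponent: neighbor-only LVC sum (full window sum minus own LVC)
    s = np.zeros_like(lvc)
    for i in range(ny):
        for j in range(nx):
            s[i, j] = (
                sum(lvc[p, q] for p, q in _window_coords(i, j, ny, nx, pad))
                - lvc[i, j]
            )
    zeta = np.exp(s)
    omega = np.zeros_like(zeta)
    for i in range(ny):
        for j in range(nx):
            omega[i, j] = zeta[i, j] / sum(
                zeta[p, q] for p, q in _window_coords(i, j, ny, nx, pad)
            )

    phi = np.zeros_like(omega)
    for i in range(ny):
        for j in range(nx):
            x, m = pixels[i, j], xbar[i, j]
            if abs(x - m) <= EQ_RTOL * max(abs(x), abs(m)):
                phi[i, j] = 0.0
            elif m < x:
                phi[i, j] = 2.0 + omega[i, j]
            else:
                phi[i, j] = 2.0 - omega[i, j]

    phi_max = phi.max()
    xi = np.zeros_like(pixels, dtype=float)
    for i in range(ny):
        for j in range(nx):
            nb = (
                sum(pixels[p, q] for p, q in _window_coords(i, j, ny, nx, pad))
                - pixels[i, j]
            )
            xi[i, j] = (pixels[i, j] + (1.0 + phi_max) / (n_r - 1) * nb) / (
                2.0 + phi_max
            )
    return lvc, omega, phi, xi


def brute_kernel_fcm(
    x: np.ndarray,
    c: int,
    m: float,
    sigma: float,
    epsilon: float = 1e-3,
    max_iter: int = 100,
):
    """Nested-loop kernel FCM on a 1-D grayscale vector.

    Mirrors the engine's conventions: initial centers spread evenly over the
    1st-99th percentile range, center update at the previous centers,
    membership update after, stop on max |du| < epsilon or the cap.
    Returns (centers, memberships).
    """
    x = [float(v) for v in x]
    n = len(x)

    def kern(a, b):
        return math.exp(-((a - b) ** 2) / (2.0 * sigma**2))

    lo, hi = np.percentile(x, [1.0, 99.0])
    centers = [lo + (hi - lo) * k / (c - 1) for k in range(c)]

    def memberships(centers):
        u = [[0.0] * c for _ in range(n)]
        for i in range(n):
            d = [1.0 - kern(x[i], centers[j]) for j in range(c)]
            zeros = [j for j in range(c) if d[j] <= 0.0]
            if zeros:
                for j in zeros:
                    u[i][j] = 1.0 / len(zeros)
            else:
                for j in range(c):
                    tot = 0.0
                    for k in range(c):
                        tot += (d[j] / d[k]) ** (1.0 / (m - 1.0))
                    u[i][j] = 1.0 / tot
        return u

    u = memberships(centers)
    for _ in range(max_iter):
        new_centers = []
        for j in range(c):
            num = den = 0.0
            for i in range(n):
                w = (u[i][j] ** m) * kern(x[i], centers[j])
                num += w * x[i]
                den += w
            new_centers.append(num / den)
        centers = new_centers
        u_new = memberships(centers)
        delta = max(
            abs(u_new[i][j] - u[i][j]) for i in range(n) for j in range(c)
        )
        u = u_new
        if delta < epsilon:
            break
    return np.array(centers), np.array(u)


def brute_arkfcm_objective(x, xbar, phi, u, centers, m, sigma):
    """Nested-loop evaluation of the clustering objective."""
    total = 0.0
    for i in range(len(x)):
        for j in range(len(centers)):
            kx = math.exp(-((x[i] - centers[j]) ** 2) / (2.0 * sigma**2))
            kb = math.exp(-((xbar[i] - centers[j]) ** 2) / (2.0 * sigma**2))
            total += (u[i, j] ** m) * (2.0 * (1.0 - kx) + 2.0 * phi[i] * (1.0 - kb))
    return total


def brute_arkfcm_center_step(x, xbar, phi, u, centers, m, sigma):
    """Nested-loop fixed-point center update."""
    c = len(centers)
    out = []
    for j in range(c):
        num = den = 0.0
        for i in range(len(x)):
            kx = math.exp(-((x[i] - centers[j]) ** 2) / (2.0 * sigma**2))
            kb = math.exp(-((xbar[i] - centers[j]) ** 2) / (2.0 * sigma**2))
            w = u[i, j] ** m
            num += w * (kx * x[i] + phi[i] * kb * xbar[i])
            den += w * (kx + phi[i] * kb)
        out.append(num / den)
    return np.array(out)


def brute_arkfcm_membership_step(x, xbar, phi, centers, m, sigma):
    """Nested-loop membership update."""
    n, c = len(x), len(centers)
    u = np.zeros((n, c))
    for i in range(n):
        d = []
        for j in range(c):
            kx = math.exp(-((x[i] - centers[j]) ** 2) / (2.0 * sigma**2))
            kb = math.exp(-((xbar[i] - centers[j]) ** 2) / (2.0 * sigma**2))
            d.append((1.0 - kx) + phi[i] * (1.0 - kb))
        zeros = [j for j in range(c) if d[j] <= 0.0]
        if zeros:
            for j in zeros:
                u[i, j] = 1.0 / len(zeros)
        else:
            for j in range(c):
                u[i, j] = 1.0 / sum(
                    (d[j] / d[k]) ** (1.0 / (m - 1.0)) for k in range(c)
                )
    return u


def brute_entropy_measure(pixels: np.ndarray, labels: np.ndarray, class_ids):
    """Histogram-by-dictionary entropy measure on an integer-valued image."""
    areas = {}
    hists = {}
    for c in class_ids:
        vals = pixels[labels == c]
        areas[c] = vals.size
        h = {}
        for v in vals:
            h[float(v)] = h.get(float(v), 0) + 1
        hists[c] = h
    s_total = sum(areas.values())
    e = 0.0
    for c in class_ids:
        if areas[c] == 0:
            continue
        w = areas[c] / s_total
        h_region = 0.0
        for cnt in hists[c].values():
            p = cnt / areas[c]
            h_region -= p * math.log(p)
        e += w * h_region - w * math.log(w)
    return e
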