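"""Shape descriptors on object masks: central and Zernike moments.

Coordinate convention is row-major and 0-based: ``CentralMoment_p_q`` raises
the row offset to p and the column offset to q. Zernike magnitudes are
computed on the object's indicator mapped onto its minimum enclosing circle
scaled to the unit disk, normalised so the full disk has |A00| = 1;
magnitudes are rotation-invariant.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "central_moments",
    "zernike_moments",
    "zernike_indices",
    "minimum_enclosing_circle",
]


def _mask_values(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mask = np.asarray(mask)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("object mask is empty")
    vals = mask[rows, cols].astype(float)
    return rows.astype(float), cols.astype(float), vals


def central_moments(mask: np.ndarray, max_order: int = 4) -> dict[tuple[int, int], float]:
    """Central moments μ_pq = Σ (r − r̄)^p (c − c̄)^q over the binary mask.

    Returns all (p, q) with 0 ≤ p, q ≤ ``max_order``; μ00 is the area and
    every μ_pq is exactly translation-invariant.
    """
    rows, cols, _ = _mask_values(np.asarray(mask) > 0)
    dr = rows - rows.mean()
    dc = cols - cols.mean()
    rp = np.vander(dr, max_order + 1, increasing=True)  # dr**p columns
    cp = np.vander(dc, max_order + 1, increasing=True)
    table = rp.T @ cp  # table[p, q] = Σ dr^p dc^q
    return {(p, q): float(table[p, q]) for p in range(max_order + 1) for q in range(max_order + 1)}


# ---------------------------------------------------------------------------
# minimum enclosing circle (Welzl-style incremental algorithm)
# ---------------------------------------------------------------------------


def _circle_from2(a, b):
    c = (a + b) / 2.0
    return c, float(np.hypot(*(a - c)))


def _circle_from3(a, b, c):
    ax, ay = a
    bx, by = b
    cx, cy = c
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < 1e-12:
        return None
    ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay) + (cx**2 + cy**2) * (ay - by)) / d
    uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx) + (cx**2 + cy**2) * (bx - ax)) / d
    center = np.array([ux, uy])
    return center, float(np.hypot(*(a - center)))


def _in_circle(circle, p, tol=1e-9) -> bool:
    c, r = circle
    return np.hypot(*(p - c)) <= r + tol


def minimum_enclosing_circle(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Smallest circle containing all 2-D points: ``(center, radius)``.

    The circle is unique, so the deterministic processing order does not
    affect the result. Points are reduced to their convex hull first when
    numerous.
    """
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    if pts.shape[0] == 1:
        return pts[0].copy(), 0.0
    if pts.shape[0] > 16:
        try:
            from scipy.spatial import ConvexHull

            pts = pts[ConvexHull(pts).vertices]
        except Exception:  # collinear degeneracies fall through to all points
            pass
    circle = _circle_from2(pts[0], pts[1])
    for i, p in enumerate(pts):
        if _in_circle(circle, p):
            continue
        circle = (p.copy(), 0.0)
        for j in range(i):
            q = pts[j]
            if _in_circle(circle, q):
                continue
            circle = _circle_from2(p, q)
            for k in range(j):
                s = pts[k]
                if _in_circle(circle, s):
                    continue
                c3 = _circle_from3(p, q, s)
                if c3 is not None:
                    circle = c3
    return circle


# ---------------------------------------------------------------------------
# Zernike moments
# ---------------------------------------------------------------------------


def zernike_indices(max_degree: int = 9) -> list[tuple[int, int]]:
    """Valid (n, m) pairs with 0 ≤ m ≤ n ≤ max_degree and n − m even."""
    return [(n, m) for n in range(max_degree + 1) for m in range(n + 1) if (n - m) % 2 == 0]


def _radial_poly(n: int, m: int, rho: np.ndarray) -> np.ndarray:
    out = np.zeros_like(rho)
    for s in range((n - m) // 2 + 1):
        coef = (
            (-1) ** s
            * math.factorial(n - s)
            / (
                math.factorial(s)
                * math.factorial((n + m) // 2 - s)
                * math.factorial((n - m) // 2 - s)
            )
        )
        out += coef * rho ** (n - 2 * s)
    return out


def zernike_moments(
    mask: np.ndarray,
    max_degree: int = 9,
    indices: list[tuple[int, int]] | None = None,
    center: tuple[float, float] | None = None,
    radius: float | None = None,
) -> dict[tuple[int, int], float]:
    """Zernike moment magnitudes |A_nm| of an object mask.

    The mask (binary, or fractional pixel coverage in [0, 1]) is mapped
    onto its minimum enclosing circle scaled to the unit disk;
    ``A_nm = (n+1)/π · Σ w · V*_nm(ρ, θ) · ΔA`` with ΔA the pixel area in
    unit-disk units, so the full disk gives |A00| = 1. Only magnitudes are
    returned (rotation-invariant). ``center``/``radius`` override the
    enclosing-circle geometry, e.g. for analytically known shapes.
    """
    if indices is None:
        indices = zernike_indices(max_degree)
    else:
        for n, m in indices:
            if not (0 <= m <= n) or (n - m) % 2 != 0:
                raise ValueError(f"invalid Zernike index (n={n}, m={m}): need 0<=m<=n, n-m even")
    rows, cols, weights = _mask_values(mask)
    if center is None or radius is None:
        pts = np.column_stack([rows, cols])
        c, r = minimum_enclosing_circle(pts)
        center = (float(c[0]), float(c[1])) if center is None else center
        radius = max(r, 1.0) if radius is None else radius
    dr = rows - center[0]
    dc = cols - center[1]
    rho = np.sqrt(dr**2 + dc**2) / radius
    theta = np.arctan2(dr, dc)
    d_area = 1.0 / radius**2

    out: dict[tuple[int, int], float] = {}
    for n, m in indices:
        rad = _radial_poly(n, m, rho)
        if m == 0:
            integral = complex((weights * rad).sum(), 0.0)
        else:
            integral = complex(
                (weights * rad * np.cos(m * theta)).sum(),
                -(weights * rad * np.sin(m * theta)).sum(),
            )
        a_nm = (n + 1) / np.pi * integral * d_area
        out[(n, m)] = abs(a_nm)
    return out
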