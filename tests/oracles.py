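"""Independent reference implementations used only to check the package.

Deliberately naive: plain nested loops over refined polylines for the
Gauss double integral, and full span enumeration for thread search.  These
share no code with the package internals they validate.
"""

from __future__ import annotations

import numpy as np


def refine_polyline(points: np.ndarray, factor: int = 20) -> np.ndarray:
    """Subdivide every segment of an open polyline into `factor` pieces."""
    points = np.asarray(points, dtype=float)
    out = [points[0]]
    for a, b in zip(points[:-1], points[1:]):
        for k in range(1, factor + 1):
            out.append(a + (b - a) * k / factor)
    return np.array(out)


def gauss_double_sum(curve_a: np.ndarray, curve_b: np.ndarray) -> float:
    """Direct midpoint-rule Gauss integral between two open polylines."""
    total = 0.0
    for a0, a1 in zip(curve_a[:-1], curve_a[1:]):
        ra = 0.5 * (a0 + a1)
        da = a1 - a0
        for b0, b1 in zip(curve_b[:-1], curve_b[1:]):
            rb = 0.5 * (b0 + b1)
            db = b1 - b0
            diff = ra - rb
            norm = np.sqrt(diff @ diff)
            if norm == 0.0:
                raise ZeroDivisionError("coincident midpoints")
            total += diff @ np.cross(da, db) / norm**3
    return total / (4.0 * np.pi)


def refined_gauss(curve_a: np.ndarray, curve_b: np.ndarray, factor: int = 20) -> float:
    """Gauss double integral of two open curves at `factor`-fold refinement."""
    return gauss_double_sum(refine_polyline(curve_a, factor), refine_polyline(curve_b, factor))


def closed_linking(curve_a: np.ndarray, curve_b: np.ndarray) -> float:
    """Brute-force linking number of two closed polygons (implicit closure)."""

    def close(c):
        c = np.asarray(c, dtype=float)
        return c if np.allclose(c[0], c[-1]) else np.vstack([c, c[0]])

    return gauss_double_sum(close(curve_a), close(curve_b))


def segment_kernel(points: np.ndarray) -> np.ndarray:
    """Pairwise segment integrand built with explicit loops (no shared code)."""
    points = np.asarray(points, dtype=float)
    mids = 0.5 * (points[1:] + points[:-1])
    bonds = points[1:] - points[:-1]
    n = len(bonds)
    kern = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            diff = mids[a] - mids[b]
            norm = np.sqrt(diff @ diff)
            val = diff @ np.cross(bonds[a], bonds[b]) / norm**3 / (4.0 * np.pi)
            kern[a, b] = kern[b, a] = val
    return kern


def enumerate_best_thread(points, i1, i2, side, mj):
    """Direct evaluation of every legal span's G' from the raw kernel block.

    Exhaustive over all (j1, j2): no prefix-sum or scanning shortcut.
    Ties broken by smallest j1 then j2.  Returns (j1, j2, value) or None.
    """
    kern = segment_kernel(points)
    n = len(points)
    lo, hi = (0, i1) if side == "N" else (i2, n - 1)
    best = None
    for j1 in range(lo, hi - mj + 1):
        for j2 in range(j1 + mj, hi + 1):
            val = float(kern[i1:i2, j1:j2].sum())
            if (
                best is None
                or abs(val) > abs(best[2]) + 1e-12
                or (abs(val) >= abs(best[2]) - 1e-12 and (j1, j2) < best[:2])
            ):
                best = (j1, j2, val)
    return best


def exhaustive_best_thread(points, i1, i2, side, mj):
    """Max-|G'| thread by enumerating every legal span; (j1, j2, value) or None.

    Ties broken by smallest j1, then smallest j2 (matching the contract of
    the function under test).
    """
    n = len(points)
    loop_curve = points[i1 : i2 + 1]
    if side == "N":
        lo, hi = 0, i1
    else:
        lo, hi = i2, n - 1
    best = None
    for j1 in range(lo, hi - mj + 1):
        for j2 in range(j1 + mj, hi + 1):
            val = gauss_double_sum(loop_curve, points[j1 : j2 + 1])
            if (
                best is None
                or abs(val) > abs(best[2]) + 1e-12
                or (abs(val) >= abs(best[2]) - 1e-12 and (j1, j2) < best[:2])
            ):
                best = (j1, j2, val)
    return best
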