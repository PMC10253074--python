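r"""Gaussian entanglement of open chain portions and per-domain indicators.

The linking number of two closed oriented curves is the Gauss double
integral

    G = (1/4pi) oint oint (r_i - r_j) / |r_i - r_j|^3 . (dr_i x dr_j)

an integer topological invariant.  For a discretized open chain with
alpha-carbon positions r_k, the same integrand evaluated over two
non-overlapping chain portions gives the real-valued *Gaussian
entanglement* G'.  With segment midpoints R_a = (r_{a+1} + r_a)/2 and bond
vectors dR_a = r_{a+1} - r_a,

    G'(portion_i, portion_j)
        = (1/4pi) sum_a sum_b (R_a - R_b)/|R_a - R_b|^3 . (dR_a x dR_b)

where a runs over the segments of one portion and b over the other.  A
*loop* is a portion closed by a native contact between its end residues; a
*thread* is any portion of at least ``MJ`` residues lying entirely on the
N- or C-terminal side of the loop.  |G'| near an integer m signals the
thread winding m times through the loop; the sign gives the chirality of
the winding with the chain oriented N to C.

Per domain, GN' (GC') is the signed G' of the maximum-modulus loop/N-thread
(C-thread) pair over all loops, and Gmax' is whichever of the two has the
larger modulus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contacts import ContactMap
from .structure_io import Backbone

MI = 4  # minimum loop span i2 - i1
MJ = 10  # minimum thread span j2 - j1
ENTANGLED_THRESHOLD = 1.0

_TIE_TOL = 1e-12

__all__ = [
    "SegmentGeometry",
    "Loop",
    "Thread",
    "LoopThreadResult",
    "EntanglementProfile",
    "segment_geometry",
    "kernel_matrix",
    "gaussian_entanglement",
    "linking_number_closed",
    "best_thread",
    "domain_profile",
    "MI",
    "MJ",
    "ENTANGLED_THRESHOLD",
]


@dataclass
class SegmentGeometry:
    """Midpoints and bond vectors of the N-1 virtual bonds of a chain."""

    midpoints: np.ndarray  # (N-1, 3)
    bonds: np.ndarray  # (N-1, 3)

    @property
    def n_segments(self) -> int:
        return len(self.bonds)


@dataclass(frozen=True)
class Loop:
    """Chain portion [i1, i2] closed by a native contact between i1 and i2."""

    i1: int
    i2: int

    def __post_init__(self) -> None:
        if self.i2 - self.i1 < MI:
            raise ValueError(f"loop ({self.i1},{self.i2}) shorter than {MI}")


@dataclass(frozen=True)
class Thread:
    """Chain portion [j1, j2] on one side of a loop."""

    j1: int
    j2: int
    side: str  # "N" or "C"


@dataclass
class LoopThreadResult:
    loop: Loop
    n_thread: Thread | None
    gn: float
    c_thread: Thread | None
    gc: float


@dataclass
class EntanglementProfile:
    """Per-domain signed entanglement indicators and their argmax pairs."""

    domain_id: str
    n_residues: int
    gn: float
    gc: float
    gmax: float
    gn_pair: tuple[Loop, Thread] | None
    gc_pair: tuple[Loop, Thread] | None
    max_side: str  # "N", "C" or "" when no loop exists
    no_loops: bool = False
    labels: dict | None = None

    @property
    def entangled(self) -> bool:
        return abs(self.gmax) >= ENTANGLED_THRESHOLD


def segment_geometry(points: np.ndarray) -> SegmentGeometry:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
        raise ValueError("need an (N>=2, 3) coordinate array")
    bonds = np.diff(pts, axis=0)
    if (np.linalg.norm(bonds, axis=1) == 0).any():
        raise ValueError("zero-length bond")
    mids = 0.5 * (pts[1:] + pts[:-1])
    return SegmentGeometry(midpoints=mids, bonds=bonds)


def _kernel_block(
    mids_a: np.ndarray, bonds_a: np.ndarray, mids_b: np.ndarray, bonds_b: np.ndarray
) -> np.ndarray:
    """Pairwise Gauss integrand (1/4pi) (Ra-Rb)/|Ra-Rb|^3 . (dRa x dRb)."""
    diff = mids_a[:, None, :] - mids_b[None, :, :]
    dist3 = np.linalg.norm(diff, axis=2) ** 3
    cross = np.cross(bonds_a[:, None, :], bonds_b[None, :, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.einsum("abk,abk->ab", diff, cross) / dist3
    return out / (4.0 * np.pi)


def kernel_matrix(geometry: SegmentGeometry) -> np.ndarray:
    """Dense (N-1, N-1) matrix of pairwise segment contributions; diagonal 0."""
    k = _kernel_block(
        geometry.midpoints, geometry.bonds, geometry.midpoints, geometry.bonds
    )
    np.fill_diagonal(k, 0.0)
    bad = ~np.isfinite(k)
    if bad.any():
        # coincident midpoints of distinct segments: zero-measure configuration
        raise FloatingPointError("coincident segment midpoints in kernel")
    return k


def gaussian_entanglement(
    geometry: SegmentGeometry,
    span_a: tuple[int, int],
    span_b: tuple[int, int],
) -> float:
    """G' between residue portions [a1, a2] and [b1, b2] of one chain.

    A portion [p, q] (residue indices, inclusive) contributes its segments
    p .. q-1.  The two portions must not overlap.
    """
    a1, a2 = span_a
    b1, b2 = span_b
    n_seg = geometry.n_segments
    for p, q in ((a1, a2), (b1, b2)):
        if not (0 <= p < q <= n_seg):
            raise ValueError(f"span ({p},{q}) out of bounds for {n_seg + 1} residues")
    if not (a2 <= b1 or b2 <= a1):
        raise ValueError(f"overlapping spans {span_a} and {span_b}")
    block = _kernel_block(
        geometry.midpoints[a1:a2],
        geometry.bonds[a1:a2],
        geometry.midpoints[b1:b2],
        geometry.bonds[b1:b2],
    )
    return float(block.sum())


def linking_number_closed(curve_a: np.ndarray, curve_b: np.ndarray) -> float:
    """Discretized Gauss linking number of two closed polygons.

    Each curve is an (n, 3) vertex array; the closing segment from the last
    vertex back to the first is added implicitly (a repeated first vertex is
    tolerated).  Converges to the integer linking number as the polygons are
    refined.
    """
    va = _close(np.asarray(curve_a, dtype=float))
    vb = _close(np.asarray(curve_b, dtype=float))
    if {tuple(p) for p in va} & {tuple(p) for p in vb}:
        raise ValueError("curves share a vertex")
    ga = segment_geometry(va)
    gb = segment_geometry(vb)
    return float(
        _kernel_block(ga.midpoints, ga.bonds, gb.midpoints, gb.bonds).sum()
    )


def _close(vertices: np.ndarray) -> np.ndarray:
    if np.allclose(vertices[0], vertices[-1]):
        return vertices
    return np.vstack([vertices, vertices[0]])


def _scan_side(
    prefix: np.ndarray, lo: int, hi: int, mj: int
) -> tuple[int, int, float] | None:
    """Maximum-|sum| contiguous span with minimum length over prefix sums.

    Candidate threads are residue spans [j1, j2] with lo <= j1, j2 <= hi and
    j2 - j1 >= mj; the span's G' is prefix[j2] - prefix[j1].  Returns
    (j1, j2, value) with ties (|G'| equal to 1e-12) broken by smallest j1
    then smallest j2; None if the side cannot host a legal span.
    """
    if hi - lo < mj:
        return None
    best: tuple[int, int, float] | None = None
    min_idx = max_idx = lo
    for j2 in range(lo + mj, hi + 1):
        # running extrema over admissible j1 <= j2 - mj (earliest index kept)
        j1_cand = j2 - mj
        if prefix[j1_cand] < prefix[min_idx]:
            min_idx = j1_cand
        if prefix[j1_cand] > prefix[max_idx]:
            max_idx = j1_cand
        for j1 in (min_idx, max_idx):
            v = prefix[j2] - prefix[j1]
            if (
                best is None
                or abs(v) > abs(best[2]) + _TIE_TOL
                or (abs(v) >= abs(best[2]) - _TIE_TOL and (j1, j2) < best[:2])
            ):
                best = (j1, j2, v)
    return best


def best_thread(
    kernel: np.ndarray, loop: Loop, side: str, mj: int = MJ
) -> tuple[Thread, float] | None:
    """Thread maximizing |G'| with a given loop, on the N- or C-terminal side.

    Equivalent to exhaustive enumeration of all contiguous spans [j1, j2]
    with j2 - j1 >= mj on that side, but runs in O(N) per loop: the G' of a
    candidate span is a contiguous sum of the per-segment totals
    g(b) = sum_{a in loop} K[a, b], handled with prefix sums.
    """
    n_res = kernel.shape[0] + 1
    g = kernel[loop.i1 : loop.i2, :].sum(axis=0)
    prefix = np.concatenate([[0.0], np.cumsum(g)])
    if side == "N":
        hit = _scan_side(prefix, 0, loop.i1, mj)
    elif side == "C":
        hit = _scan_side(prefix, loop.i2, n_res - 1, mj)
    else:
        raise ValueError(f"side must be 'N' or 'C', got {side!r}")
    if hit is None:
        return None
    j1, j2, val = hit
    return Thread(j1, j2, side), float(val)


def domain_profile(
    backbone: Backbone,
    contacts: ContactMap,
    mi: int = MI,
    mj: int = MJ,
) -> EntanglementProfile:
    """Per-domain entanglement indicators GN', GC', Gmax'.

    Every native contact (i1, i2) with i2 - i1 >= mi opens a loop; for each
    loop the maximum-|G'| thread is found on both sides; GN' and GC' are
    the signed values of the overall maximum-modulus pair per side, and
    Gmax' is the one with the larger modulus (N side wins exact ties).
    Deterministic: ties between pairs are broken by smallest loop (i1, i2)
    then smallest thread (j1, j2).
    """
    geometry = segment_geometry(backbone.ca)
    kernel = kernel_matrix(geometry)

    best_by_side: dict[str, tuple[float, Loop, Thread] | None] = {"N": None, "C": None}
    any_loop = False
    for i1, i2 in contacts:
        if i2 - i1 < mi:
            continue
        loop = Loop(i1, i2)
        any_loop = True
        for side in ("N", "C"):
            hit = best_thread(kernel, loop, side, mj=mj)
            if hit is None:
                continue
            thread, val = hit
            cur = best_by_side[side]
            if cur is None or abs(val) > abs(cur[0]) + _TIE_TOL:
                best_by_side[side] = (val, loop, thread)

    gn_hit = best_by_side["N"]
    gc_hit = best_by_side["C"]
    gn = gn_hit[0] if gn_hit else 0.0
    gc = gc_hit[0] if gc_hit else 0.0
    if abs(gn) >= abs(gc):
        gmax, max_side = gn, ("N" if gn_hit else "")
    else:
        gmax, max_side = gc, "C"
    return EntanglementProfile(
        domain_id=backbone.domain_id,
        n_residues=len(backbone),
        gn=gn,
        gc=gc,
        gmax=gmax,
        gn_pair=(gn_hit[1], gn_hit[2]) if gn_hit else None,
        gc_pair=(gc_hit[1], gc_hit[2]) if gc_hit else None,
        max_side=max_side,
        no_loops=not any_loop,
    )
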