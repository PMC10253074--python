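"""Synthetic backbones with known entanglement ground truth.

The generator builds single open chains whose Gaussian entanglement is
known by construction, written as valid PDB files, so the whole pipeline
(parsing, contact detection, loop/thread search, survey statistics) can be
tested without downloading any structure.

Construction.  The *loop* is a near-circular arc of alpha carbons in the
z = 0 plane whose two end residues face each other across a short gap and
carry dummy side-chain (CB) atoms closer than the contact cutoff - this
forces exactly the intended closing contact through the heavy-atom rule.
A *thread* section is a helix that winds ``m`` times around the loop wire
(one linking unit per turn); its handedness sets the chirality sign.  For
non-entangled chains the thread performs only a fraction of a turn, so it
picks up a partial winding (|G'| ~ 0.2, the shoulder value typical of
non-entangled native domains).  All entry/exit legs and connectors are
routed exactly in the loop plane: a curve coplanar with the loop has
identically zero Gaussian coupling with it (every scalar triple product
of coplanar vectors vanishes), so the legs cannot contaminate the planted
winding number.

Ground truth: with the chain oriented N to C, a noiseless spec with
winding number m, chirality s and a given side yields GN' (or GC') within
a few hundredths of s*m, and round(Gmax') = s*m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd

from .contacts import ContactMap, contact_map
from .entanglement_core import MI, MJ, domain_profile
from .structure_io import Backbone, read_structure

CA_SPACING = 3.8
HELIX_RADIUS = 8.0  # tube radius of the thread helix around the loop wire, A
HELIX_PITCH = 6.0  # axial drift per turn; keeps successive turns out of contact
GAP_CHORD = 5.6  # CA-CA distance across the forced closing contact, A
CB_OFFSET = 1.0  # dummy CB placed this far from its CA toward the partner
PARTIAL_TURNS = 0.3  # fractional wire winding of a non-entangled thread
ROUT_FACTOR = 2.5  # connector arc radius, in loop radii
LEAD_SKEW = math.radians(15)  # lead direction offset away from the connector arc
LEAD_SKEW_FRACTIONAL = math.radians(30)  # larger offset clears the open helix end

# In-plane layout: the loop gap sits at angle pi; each side's connector,
# helix and lead live in a private angular sector so the paths never cross.
_SIDE_LAYOUT = {
    #      helix wire angle        arc dir  drift  lead skew
    "N": (math.radians(250), +1, +1, +1),
    "C": (math.radians(110), -1, -1, -1),
}

# Measured once from the refined Gauss-integral oracle: the chirality sign
# produced by helix handedness h = +1, per side and winding kind.  Flipping
# the handedness mirrors the helix about the loop plane and flips the sign
# exactly (the loop is planar), so any requested sign is reachable.
_SIGN_WITH_H_PLUS = {
    ("N", "full"): 1,
    ("C", "full"): -1,
    ("N", "partial"): -1,
    ("C", "partial"): 1,
}

__all__ = [
    "TopologySpec",
    "ThreadedLoopFixture",
    "make_threaded_loop",
    "make_two_sided_chain",
    "make_closed_pair",
    "make_planar_chain",
    "write_synthetic_pdb",
    "make_cohort",
    "cohort_profiles",
    "COHORT_CLASSES",
]


@dataclass(frozen=True)
class TopologySpec:
    """Recipe for one synthetic threaded-loop chain."""

    m: int = 1
    sign: int = 1
    side: str = "N"
    loop_size: int = 40
    thread_length: int = 20
    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 0:
            raise ValueError("winding number m must be >= 0")
        if self.sign not in (1, -1):
            raise ValueError("sign must be +1 or -1")
        if self.side not in ("N", "C"):
            raise ValueError("side must be 'N' or 'C'")
        if self.loop_size - 1 < MI:
            raise ValueError(f"loop span below {MI}")
        if self.thread_length < MJ:
            raise ValueError(f"thread length below {MJ}")
        radius = self.loop_size * CA_SPACING / (2 * math.pi)
        if radius < HELIX_RADIUS + 5.0:
            raise ValueError(
                f"loop of {self.loop_size} residues too tight to host the thread helix"
            )


@dataclass
class ThreadedLoopFixture:
    backbone: Backbone
    contacts: ContactMap
    loop: tuple[int, int]
    expected_gmax: float
    spec: TopologySpec


# -- low-level geometry ----------------------------------------------------


def _chaikin(points: np.ndarray, iterations: int = 2) -> np.ndarray:
    """Corner-cutting smoothing; endpoints pinned.

    Applied before resampling so that chord lengths across path corners
    stay close to the arc-length spacing.  Cutting a corner between
    coplanar segments keeps the result in the same plane.
    """
    pts = np.asarray(points, dtype=float)
    for _ in range(iterations):
        q = 0.75 * pts[:-1] + 0.25 * pts[1:]
        r = 0.25 * pts[:-1] + 0.75 * pts[1:]
        mid = np.empty((2 * len(q), 3))
        mid[0::2], mid[1::2] = q, r
        pts = np.vstack([pts[0], mid, pts[-1]])
    return pts


def _resample(waypoints: np.ndarray, spacing: float = CA_SPACING) -> np.ndarray:
    """Points every `spacing` of arc length along a dense polyline, start included."""
    seg = np.linalg.norm(np.diff(waypoints, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.arange(0.0, arclen[-1], spacing)
    out = np.empty((len(targets), 3))
    for k, s in enumerate(targets):
        i = np.searchsorted(arclen, s, side="right") - 1
        i = min(i, len(seg) - 1)
        t = (s - arclen[i]) / seg[i] if seg[i] > 0 else 0.0
        out[k] = waypoints[i] + t * (waypoints[i + 1] - waypoints[i])
    return out


def _chord_resample(waypoints: np.ndarray, spacing: float = CA_SPACING) -> np.ndarray:
    """Walk a polyline emitting points exactly `spacing` apart in a straight line.

    Unlike arc-length resampling this keeps consecutive-point (virtual
    bond) distances at the CA spacing even across curved stretches, which
    is what protein backbones do.
    """
    dense = _resample(waypoints, spacing=0.25)
    out = [dense[0]]
    k = 0
    while True:
        d = np.linalg.norm(dense[k:] - out[-1], axis=1)
        ahead = np.nonzero(d >= spacing)[0]
        if not len(ahead):
            break
        j = k + ahead[0]
        # interpolate on the segment crossing the spacing sphere
        a, b = dense[j - 1], dense[j]
        da, db = np.linalg.norm(a - out[-1]), np.linalg.norm(b - out[-1])
        t = (spacing - da) / (db - da) if db > da else 1.0
        out.append(a + t * (b - a))
        k = j
    return np.array(out)


def _loop_points(n_loop: int) -> tuple[np.ndarray, float]:
    """Loop arc in the z=0 plane; returns (points, radius).

    The gap sits at angle pi; traversal is counterclockwise (seen from +z)
    from pi + delta/2 around through 0 back to pi - delta/2.
    """
    radius = n_loop * CA_SPACING / (2 * math.pi)
    delta = 2 * math.asin(GAP_CHORD / (2 * radius))
    theta = math.pi + delta / 2 + np.arange(n_loop) * (2 * math.pi - delta) / (n_loop - 1)
    return np.column_stack(
        [radius * np.cos(theta), radius * np.sin(theta), np.zeros(n_loop)]
    ), radius


def _helix_points(
    radius: float,
    phi: float,
    turns: float,
    handedness: int,
    drift_sign: int,
    points_per_turn: int = 40,
) -> np.ndarray:
    """Dense helix waypoints winding around the loop wire at angle ``phi``.

    The helix axis is the local loop tangent; parameter t runs 0 ..
    2*pi*turns with the t = 0 (connector) end lying exactly in the loop
    plane at planar radius R + rho.  ``turns`` may be fractional for a
    partial (non-entangled) thread.  ``drift_sign`` sets which tangent
    direction the winding advances along, so the far (lead) end sits on
    the side away from the loop gap.
    """
    n_hat = np.array([math.cos(phi), math.sin(phi), 0.0])
    tau_hat = np.array([-math.sin(phi), math.cos(phi), 0.0])
    z_hat = np.array([0.0, 0.0, 1.0])
    center = radius * n_hat
    n_pts = max(int(points_per_turn * turns), 12)
    t = np.linspace(0.0, 2 * math.pi * turns, n_pts)
    drift = drift_sign * HELIX_PITCH * t / (2 * math.pi)
    return (
        center
        + HELIX_RADIUS * (np.cos(t)[:, None] * n_hat + handedness * np.sin(t)[:, None] * z_hat)
        + drift[:, None] * tau_hat
    )


def _side_waypoints(
    side: str,
    junction_angle: float,
    radius: float,
    turns: float,
    handedness: int,
    lead_length: float,
) -> np.ndarray:
    """Dense waypoints from the loop junction outward to the chain terminus.

    junction -> radial out to the connector radius -> in-plane arc to the
    helix's t = 0 end -> helix (winding around the wire) -> straight lead
    away from the loop.  Everything except the helix (and, for fractional
    windings, the lead) lies exactly in the loop plane, hence couples to
    the loop with identically zero Gaussian entanglement.
    """
    phi, arc_dir, drift_sign, skew_sign = _SIDE_LAYOUT[side]
    r_out = ROUT_FACTOR * radius
    helix = _helix_points(radius, phi, turns, handedness, drift_sign)
    near, far = helix[0], helix[-1]

    way = [np.array([radius * math.cos(junction_angle), radius * math.sin(junction_angle), 0.0])]
    for u in np.linspace(radius + 1.0, r_out, 12):
        way.append(np.array([u * math.cos(junction_angle), u * math.sin(junction_angle), 0.0]))
    # in-plane arc at r_out toward the helix near end (never crosses the gap)
    target = math.atan2(near[1], near[0])
    target = _unwrap_above(target, junction_angle) if arc_dir > 0 else _unwrap_below(
        target, junction_angle
    )
    a = junction_angle
    while (arc_dir > 0 and a < target) or (arc_dir < 0 and a > target):
        a += arc_dir * 0.03
        way.append(np.array([r_out * math.cos(a), r_out * math.sin(a), 0.0]))
    # radial in to the helix near end (in-plane: the t = 0 end has z = 0)
    r_near = math.hypot(near[0], near[1])
    for u in np.linspace(r_out, r_near, 12)[1:]:
        way.append(np.array([u * math.cos(target), u * math.sin(target), 0.0]))
    way.extend(list(helix))
    # straight lead from the far end, skewed away from the connector arc;
    # a fractional winding ends off-plane with a descending tangent, so the
    # lead continues downward to avoid folding back onto the helix
    fractional = turns != int(turns)
    skew = LEAD_SKEW_FRACTIONAL if fractional else LEAD_SKEW
    beta = math.atan2(far[1], far[0]) + skew_sign * skew
    d_hat = np.array([math.cos(beta), math.sin(beta), 0.0])
    if fractional:
        d_hat = d_hat + np.array([0.0, 0.0, -0.6 * handedness])
        d_hat /= np.linalg.norm(d_hat)
    for u in np.linspace(2.0, lead_length, 10):
        way.append(far + u * d_hat)
    # coarsen, then round the corners over a ~7 A scale so that chord
    # lengths at CA spacing never collapse at path elbows
    return _chaikin(_resample(np.array(way), spacing=7.0), iterations=3)


def _unwrap_above(target: float, ref: float) -> float:
    while target < ref:
        target += 2 * math.pi
    return target


def _unwrap_below(target: float, ref: float) -> float:
    while target > ref:
        target -= 2 * math.pi
    return target


# -- chain assembly --------------------------------------------------------


def _assemble(
    loop_size: int,
    n_side: tuple[int, int, bool] | None,
    c_side: tuple[int, int, bool] | None,
    sigma: float,
    seed: int,
    lead_residues: int = 20,
) -> tuple[np.ndarray, tuple[int, int]]:
    """CA trace with a central loop and optional N/C thread sections.

    ``n_side`` / ``c_side`` are (m, requested_sign, partial) or None.
    Returns (ca_coordinates, (i1, i2) loop residue indices).
    """
    loop_pts, radius = _loop_points(loop_size)
    delta = 2 * math.asin(GAP_CHORD / (2 * radius))
    lead_length = lead_residues * CA_SPACING

    sections: list[np.ndarray] = []
    if n_side is not None:
        m, sign, partial = n_side
        kind = "partial" if partial else "full"
        turns = PARTIAL_TURNS if partial else float(m)
        h = sign * _SIGN_WITH_H_PLUS[("N", kind)]
        way = _side_waypoints("N", math.pi + delta / 2, radius, turns, h, lead_length)
        pts = _chord_resample(way)[::-1]  # terminus ... down to the loop start
        sections.append(pts[:-1])  # the junction point is the loop start itself
    sections.append(loop_pts)
    if c_side is not None:
        m, sign, partial = c_side
        kind = "partial" if partial else "full"
        turns = PARTIAL_TURNS if partial else float(m)
        h = sign * _SIGN_WITH_H_PLUS[("C", kind)]
        way = _side_waypoints("C", math.pi - delta / 2, radius, turns, h, lead_length)
        pts = _chord_resample(way)
        sections.append(pts[1:])  # drop the duplicated loop-end junction

    ca = np.concatenate(sections)
    n_before = 0 if n_side is None else len(sections[0])
    i1, i2 = n_before, n_before + loop_size - 1

    if sigma > 0:
        rng = np.random.default_rng(seed)
        ca = ca + rng.normal(0.0, sigma, ca.shape)
    return ca, (i1, i2)


def _to_backbone(
    domain_id: str, ca: np.ndarray, loop: tuple[int, int]
) -> Backbone:
    """Wrap a CA trace as a Backbone, forcing the closing contact with CBs."""
    n = len(ca)
    i1, i2 = loop
    heavy = [ca[k][None, :].copy() for k in range(n)]
    d = ca[i2] - ca[i1]
    d = d / np.linalg.norm(d)
    cb1 = ca[i1] + CB_OFFSET * d
    cb2 = ca[i2] - CB_OFFSET * d
    heavy[i1] = np.vstack([ca[i1], cb1])
    heavy[i2] = np.vstack([ca[i2], cb2])
    return Backbone(
        domain_id=domain_id,
        ca=ca,
        residue_ids=[(k + 1, "") for k in range(n)],
        heavy=heavy,
        observed=np.ones(n, dtype=bool),
        res_names=["ALA" if k in (i1, i2) else "GLY" for k in range(n)],
    )


def make_threaded_loop(spec: TopologySpec, domain_id: str = "SYNTH") -> ThreadedLoopFixture:
    """Single open chain: one loop threaded m times on the requested side.

    m = 0 places the thread helix outside the loop (non-entangled chain
    with a small partial |G'|).  The loop sits at the chain terminus
    opposite the thread, so the other side hosts no thread at all.
    """
    partial = spec.m == 0
    side_spec = (spec.m, spec.sign, partial)
    lead = max(spec.thread_length, MJ)
    ca, loop = _assemble(
        spec.loop_size,
        side_spec if spec.side == "N" else None,
        side_spec if spec.side == "C" else None,
        spec.sigma,
        spec.seed,
        lead_residues=lead,
    )
    backbone = _to_backbone(domain_id, ca, loop)
    cmap = contact_map(backbone)
    expected = 0.0 if partial else float(spec.sign * spec.m)
    return ThreadedLoopFixture(backbone, cmap, loop, expected, spec)


def make_two_sided_chain(
    n_spec: tuple[int, int, bool] | None,
    c_spec: tuple[int, int, bool] | None,
    loop_size: int = 40,
    sigma: float = 0.0,
    seed: int = 0,
    domain_id: str = "SYNTH2",
) -> ThreadedLoopFixture:
    """Chain with a central loop and independent thread sections on both sides.

    Each side spec is (m, sign, partial); used to plant same-sign or
    opposite-sign GN'/GC' combinations for survey-statistics tests.
    """
    ca, loop = _assemble(loop_size, n_spec, c_spec, sigma, seed)
    backbone = _to_backbone(domain_id, ca, loop)
    cmap = contact_map(backbone)
    exp = 0.0
    for s in (n_spec, c_spec):
        if s is not None and not s[2] and s[0] * abs(s[1]) > abs(exp):
            exp = float(s[0] * s[1])
    return ThreadedLoopFixture(backbone, cmap, loop, exp, None)


# -- closed curves ---------------------------------------------------------


def make_closed_pair(kind: str, n_segments: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """Two closed polygons with known linking number.

    'unlinked': parallel circles ten radii apart (linking 0);
    'hopf': orthogonal interlocked circles (linking +-1);
    'double': a circle and a curve winding twice around its wire (+-2).
    """
    r = 10.0
    t = np.linspace(0.0, 2 * math.pi, n_segments, endpoint=False)
    circle = np.column_stack([r * np.cos(t), r * np.sin(t), np.zeros_like(t)])
    if kind == "unlinked":
        other = circle + np.array([0.0, 0.0, 10 * r])
    elif kind == "hopf":
        other = np.column_stack(
            [r + r * np.cos(t), np.zeros_like(t), r * np.sin(t)]
        )
    elif kind == "double":
        rho = r / 3.0
        other = np.column_stack(
            [
                (r + rho * np.cos(2 * t)) * np.cos(t),
                (r + rho * np.cos(2 * t)) * np.sin(t),
                rho * np.sin(2 * t),
            ]
        )
    else:
        raise ValueError(f"unknown kind {kind!r}")
    return circle, other


def make_planar_chain(n: int = 30, kind: str = "zigzag") -> Backbone:
    """Open chain lying entirely in one plane: every G' vanishes exactly."""
    k = np.arange(n, dtype=float)
    if kind == "zigzag":
        pts = np.column_stack([3.0 * k, 2.0 * (k % 2), np.zeros(n)])
    elif kind == "arc":
        theta = k * 0.15
        pts = np.column_stack([25 * np.cos(theta), 25 * np.sin(theta), np.zeros(n)])
    elif kind == "spiral":
        theta = k * 0.4
        rad = 5.0 + 1.5 * k
        pts = np.column_stack([rad * np.cos(theta), rad * np.sin(theta), np.zeros(n)])
    else:
        raise ValueError(f"unknown kind {kind!r}")
    return Backbone(
        domain_id=f"planar-{kind}",
        ca=pts,
        residue_ids=[(i + 1, "") for i in range(n)],
        heavy=[pts[i][None, :].copy() for i in range(n)],
        observed=np.ones(n, dtype=bool),
        res_names=["GLY"] * n,
    )


# -- PDB output ------------------------------------------------------------


def write_synthetic_pdb(backbone: Backbone, path: str) -> None:
    """Write a Backbone as a valid single-chain PDB file (CA + dummy CB atoms)."""
    if np.abs(backbone.ca).max() > 9999.999:
        raise ValueError("coordinates overflow the PDB fixed-width fields")
    st = gemmi.Structure()
    st.name = backbone.domain_id
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for k in range(len(backbone)):
        res = gemmi.Residue()
        res.name = backbone.res_names[k] if backbone.res_names else "GLY"
        res.seqid = gemmi.SeqId(backbone.residue_ids[k][0], " ")
        ca = gemmi.Atom()
        ca.name = "CA"
        ca.element = gemmi.Element("C")
        ca.pos = gemmi.Position(*backbone.ca[k])
        ca.occ = 1.0
        res.add_atom(ca)
        for extra in backbone.heavy[k][1:]:
            cb = gemmi.Atom()
            cb.name = "CB"
            cb.element = gemmi.Element("C")
            cb.pos = gemmi.Position(*extra)
            cb.occ = 1.0
            res.add_atom(cb)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# -- cohorts ---------------------------------------------------------------

# Named chain classes for planted cohorts.  Full windings use the helix
# through the loop; the opposite side carries a same-sign partial thread so
# that same-sign grouping (GN' vs GC') is well defined.
COHORT_CLASSES: dict[str, dict] = {
    "unentangled": {"n": (0, 1, True), "c": (0, 1, True)},
    "N_pos_m1": {"n": (1, 1, False), "c": (0, 1, True)},
    "C_pos_m1": {"n": (0, 1, True), "c": (1, 1, False)},
    "N_neg_m1": {"n": (1, -1, False), "c": (0, -1, True)},
    "C_neg_m1": {"n": (0, -1, True), "c": (1, -1, False)},
    "N_pos_m2": {"n": (2, 1, False), "c": (0, 1, True)},
    "C_neg_m2": {"n": (0, -1, True), "c": (2, -1, False)},
    "anti_diagonal": {"n": (1, 1, False), "c": (1, -1, False)},
}


@dataclass
class Cohort:
    fixtures: list[ThreadedLoopFixture] = field(default_factory=list)
    manifest: pd.DataFrame | None = None


def make_cohort(
    n_domains: int,
    composition: dict[str, float],
    seed: int = 0,
    sigma: float = 0.1,
    loop_size: int = 40,
) -> Cohort:
    """Cohort of synthetic chains with planted class composition.

    ``composition`` maps COHORT_CLASSES names to fractions (need not sum
    to 1; remaining mass is 'unentangled').  Class counts are the rounded
    expected counts, so the planted composition is exact up to rounding,
    not binomial.  Per-chain vertex noise uses independent substreams of
    ``seed``.
    """
    bad = set(composition) - set(COHORT_CLASSES)
    if bad:
        raise ValueError(f"unknown cohort classes: {sorted(bad)}")
    counts = {name: int(round(f * n_domains)) for name, f in composition.items()}
    total = sum(counts.values())
    if total > n_domains:
        raise ValueError("composition fractions exceed 1")
    counts["unentangled"] = counts.get("unentangled", 0) + (n_domains - total)

    rng = np.random.default_rng(seed)
    fixtures = []
    rows = []
    k = 0
    for name in sorted(counts):
        spec = COHORT_CLASSES[name]
        for _ in range(counts[name]):
            sub = int(rng.integers(0, 2**31 - 1))
            fx = make_two_sided_chain(
                spec["n"],
                spec["c"],
                loop_size=loop_size,
                sigma=sigma,
                seed=sub,
                domain_id=f"SYN{k:05d}",
            )
            fixtures.append(fx)
            rows.append(
                {
                    "domain_id": fx.backbone.domain_id,
                    "class": name,
                    "expected_gmax": fx.expected_gmax,
                    "sigma": sigma,
                    "seed": sub,
                }
            )
            k += 1
    return Cohort(fixtures=fixtures, manifest=pd.DataFrame(rows))


def cohort_profiles(cohort: Cohort) -> pd.DataFrame:
    """Run the entanglement pipeline on every cohort chain; tidy results table."""
    from .survey_stats import profiles_to_table

    profiles = []
    for fx in cohort.fixtures:
        profiles.append(domain_profile(fx.backbone, fx.contacts))
    table = profiles_to_table(profiles)
    return table.merge(cohort.manifest, on="domain_id")


def roundtrip_backbone(fixture: ThreadedLoopFixture, path: str) -> Backbone:
    """Write a fixture to PDB and read it back through structure_io."""
    from .structure_io import DomainSpec, extract_domain

    write_synthetic_pdb(fixture.backbone, path)
    atoms = read_structure(path)
    spec = DomainSpec(
        fixture.backbone.domain_id, "A", ((1, len(fixture.backbone)),)
    )
    return extract_domain(atoms, spec)
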