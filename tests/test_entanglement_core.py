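from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from gausslink.contacts import ContactMap, contact_map
from gausslink.entanglement_core import (
    Loop,
    Thread,
    best_thread,
    domain_profile,
    gaussian_entanglement,
    kernel_matrix,
    linking_number_closed,
    segment_geometry,
)
from gausslink.synthetic_data import (
    TopologySpec,
    make_closed_pair,
    make_planar_chain,
    make_threaded_loop,
)

from conftest import chain_backbone, random_chain
from oracles import exhaustive_best_thread, refined_gauss


class TestGaussianEntanglement:
    @pytest.mark.parametrize("kind", ["zigzag", "arc", "spiral"])
    def test_planar_chain_vanishes_exactly(self, kind):
        bb = make_planar_chain(30, kind)
        geom = segment_geometry(bb.ca)
        assert gaussian_entanglement(geom, (0, 10), (15, 29)) == 0.0

    def test_single_winding_matches_refined_integral(self, threaded_m1):
        ca = threaded_m1.backbone.ca
        i1, i2 = threaded_m1.loop
        geom = segment_geometry(ca)
        kern = kernel_matrix(geom)
        thread, val = best_thread(kern, Loop(i1, i2), "N")
        assert val == pytest.approx(1.0, abs=0.05)
        oracle = refined_gauss(ca[i1 : i2 + 1], ca[thread.j1 : thread.j2 + 1], factor=10)
        assert val == pytest.approx(oracle, abs=0.03)

    def test_mirror_image_negates(self, threaded_m1):
        ca = threaded_m1.backbone.ca
        i1, i2 = threaded_m1.loop
        span_a, span_b = (i1, i2), (0, i1)
        direct = gaussian_entanglement(segment_geometry(ca), span_a, span_b)
        mirrored = ca * np.array([1.0, 1.0, -1.0])
        flipped = gaussian_entanglement(segment_geometry(mirrored), span_a, span_b)
        assert flipped == -direct

    def test_symmetric_in_spans(self, rng):
        pts = random_chain(40, rng)
        geom = segment_geometry(pts)
        a, b = (0, 15), (20, 39)
        assert gaussian_entanglement(geom, a, b) == pytest.approx(
            gaussian_entanglement(geom, b, a), abs=1e-12
        )

    def test_overlapping_spans_rejected(self, rng):
        geom = segment_geometry(random_chain(30, rng))
        with pytest.raises(ValueError, match="overlap"):
            gaussian_entanglement(geom, (0, 15), (10, 29))

    def test_kernel_symmetric(self, rng):
        kern = kernel_matrix(segment_geometry(random_chain(25, rng)))
        np.testing.assert_allclose(kern, kern.T, atol=1e-12)
        assert np.all(np.diag(kern) == 0.0)


class TestClosedCurves:
    def test_separated_circles_unlinked(self):
        a, b = make_closed_pair("unlinked", 200)
        assert abs(linking_number_closed(a, b)) < 0.01

    def test_hopf_link_is_minus_one(self):
        # sign for these orientations frozen from the brute-force oracle
        a, b = make_closed_pair("hopf", 200)
        assert linking_number_closed(a, b) == pytest.approx(-1.0, abs=0.01)

    def test_double_winding_is_minus_two(self):
        a, b = make_closed_pair("double", 400)
        assert linking_number_closed(a, b) == pytest.approx(-2.0, abs=0.02)

    def test_symmetric_under_exchange(self):
        a, b = make_closed_pair("hopf", 100)
        assert linking_number_closed(a, b) == pytest.approx(
            linking_number_closed(b, a), abs=1e-12
        )

    def test_shared_vertex_rejected(self):
        a, _ = make_closed_pair("hopf", 50)
        with pytest.raises(ValueError, match="vertex"):
            linking_number_closed(a, a.copy())


class TestBestThread:
    def test_no_room_on_n_side_is_absent(self, rng):
        kern = kernel_matrix(segment_geometry(random_chain(40, rng)))
        assert best_thread(kern, Loop(9, 20), "N") is None  # N side shorter than mj
        assert best_thread(kern, Loop(9, 20), "C") is not None

    def test_equals_exhaustive_enumeration(self, rng):
        for trial in range(6):
            pts = random_chain(45, rng)
            kern = kernel_matrix(segment_geometry(pts))
            for i1, i2 in [(12, 20), (15, 30), (20, 44)]:
                for side in ("N", "C"):
                    got = best_thread(kern, Loop(i1, i2), side)
                    want = exhaustive_best_thread(pts, i1, i2, side, 10)
                    if want is None:
                        assert got is None
                    else:
                        thread, val = got
                        assert (thread.j1, thread.j2) == want[:2]
                        assert val == pytest.approx(want[2], abs=1e-9)

    def test_reported_value_matches_direct_evaluation(self, threaded_m1):
        ca = threaded_m1.backbone.ca
        i1, i2 = threaded_m1.loop
        geom = segment_geometry(ca)
        kern = kernel_matrix(geom)
        thread, val = best_thread(kern, Loop(i1, i2), "N")
        direct = gaussian_entanglement(geom, (i1, i2), (thread.j1, thread.j2))
        assert val == pytest.approx(direct, abs=1e-9)


class TestDomainProfile:
    def test_straight_chain_flagged_no_loops(self):
        pts = np.column_stack([np.arange(30) * 3.8, np.zeros(30), np.zeros(30)])
        bb = chain_backbone(pts)
        profile = domain_profile(bb, contact_map(bb))
        assert profile.no_loops
        assert profile.gn == profile.gc == profile.gmax == 0.0

    def test_gmax_is_max_modulus_side(self, threaded_m1):
        p = domain_profile(threaded_m1.backbone, threaded_m1.contacts)
        assert abs(p.gmax) == max(abs(p.gn), abs(p.gc))
        assert p.max_side == "N"
        assert p.gmax == p.gn

    def test_deterministic(self, threaded_m1):
        p1 = domain_profile(threaded_m1.backbone, threaded_m1.contacts)
        p2 = domain_profile(threaded_m1.backbone, threaded_m1.contacts)
        assert (p1.gn, p1.gc, p1.gmax) == (p2.gn, p2.gc, p2.gmax)
        assert p1.gn_pair == p2.gn_pair


class TestInvariances:
    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(seed=st.integers(0, 2**20))
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        pts = random_chain(35, rng)
        rot = Rotation.random(rng=rng).as_matrix()
        shift = rng.normal(scale=50.0, size=3)
        moved = pts @ rot.T + shift
        g0 = gaussian_entanglement(segment_geometry(pts), (0, 15), (20, 34))
        g1 = gaussian_entanglement(segment_geometry(moved), (0, 15), (20, 34))
        assert g1 == pytest.approx(g0, abs=1e-9)

    def test_scale_invariance(self, rng):
        pts = random_chain(35, rng)
        g0 = gaussian_entanglement(segment_geometry(pts), (0, 15), (20, 34))
        g1 = gaussian_entanglement(segment_geometry(pts * 7.3), (0, 15), (20, 34))
        assert g1 == pytest.approx(g0, abs=1e-9)

    def test_chain_reversal_swaps_sides_keeps_values(self, threaded_m1):
        bb = threaded_m1.backbone
        n = len(bb)
        i1, i2 = threaded_m1.loop
        rev = chain_backbone(bb.ca[::-1].copy())
        rev_contacts = ContactMap(
            [(n - 1 - i2, n - 1 - i1)],
            threaded_m1.contacts.cutoff,
            threaded_m1.contacts.min_separation,
        )
        fwd = domain_profile(bb, threaded_m1.contacts)
        bwd = domain_profile(rev, rev_contacts)
        assert bwd.gc == pytest.approx(fwd.gn, abs=1e-9)
        assert bwd.gn == pytest.approx(fwd.gc, abs=1e-9)


def test_profile_speed_contract(rng):
    """N=500 with hundreds of loops profiles in a few seconds."""
    import time

    pts = random_chain(500, rng, step=2.2)
    bb = chain_backbone(pts)
    cmap = contact_map(bb)
    assert len(cmap) > 200
    t0 = time.perf_counter()
    domain_profile(bb, cmap)
    assert time.perf_counter() - t0 < 20.0
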