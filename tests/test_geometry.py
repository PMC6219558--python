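"""Geometry: projection, side assignment, ordering and the spacing ratio."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from veinspacing.geometry import (
    GeometryError,
    LeafRecord,
    MidveinAxis,
    VeinOrigin,
    assign_sides,
    axial_position,
    compute_ratios,
    leaf_ratios,
    order_along_midvein,
)


def _origins(layout):
    """Build sided origins from (s, side) pairs laid on a straight axis."""
    return [
        VeinOrigin(leaf_id="t", x=(-1.0 if side == "left" else 1.0), y=s,
                   s=float(s), side=side)
        for s, side in layout
    ]


class TestAxialPosition:
    def test_orthogonal_projection_on_straight_axis(self):
        axis = MidveinAxis(nodes=((0, 0), (0, 100)))
        assert axial_position(axis, (5, 40)) == pytest.approx(40.0)

    def test_base_maps_to_zero(self):
        axis = MidveinAxis(nodes=((0, 0), (0, 100)))
        assert axial_position(axis, (0, 0)) == 0.0

    def test_two_segment_arc_length(self):
        axis = MidveinAxis(nodes=((0, 0), (0, 50), (50, 50)))
        assert axial_position(axis, (25, 55)) == pytest.approx(75.0)

    def test_degenerate_axis_rejected(self):
        with pytest.raises(GeometryError):
            MidveinAxis(nodes=((1, 1), (1, 1)))


class TestAssignSides:
    def test_opposite_offsets_get_opposite_sides(self):
        axis = MidveinAxis(nodes=((0, 0), (0, 100)))
        a = VeinOrigin(leaf_id="t", x=-5, y=40)
        b = VeinOrigin(leaf_id="t", x=+5, y=40)
        out = assign_sides(axis, [a, b])
        assert {o.side for o in out} == {"left", "right"}
        assert out[0].side != out[1].side

    def test_mirror_reflection_swaps_labels(self):
        axis = MidveinAxis(nodes=((0, 0), (0, 100)))
        pts = [VeinOrigin(leaf_id="t", x=x, y=y)
               for x, y in ((-3, 10), (4, 20), (-2, 30))]
        sides = [o.side for o in assign_sides(axis, pts)]
        mirrored = [VeinOrigin(leaf_id="t", x=-o.x, y=o.y) for o in pts]
        swapped = [o.side for o in assign_sides(axis, mirrored)]
        flip = {"left": "right", "right": "left"}
        assert swapped == [flip[s] for s in sides]

    def test_on_axis_origin_excluded_with_warning(self):
        axis = MidveinAxis(nodes=((0, 0), (0, 100)))
        pts = [VeinOrigin(leaf_id="t", x=0.0, y=50.0),
               VeinOrigin(leaf_id="t", x=1.0, y=60.0)]
        with pytest.warns(UserWarning, match="lies on the midvein"):
            out = assign_sides(axis, pts)
        assert len(out) == 1


class TestOrdering:
    def test_sorted_by_axial_position(self):
        out = order_along_midvein(_origins([(30, "left"), (10, "right"), (20, "left")]))
        assert [o.s for o in out] == [10, 20, 30]
        assert [o.index for o in out] == [0, 1, 2]

    def test_coincident_opposite_pair_both_retained(self):
        out = order_along_midvein(_origins([(10, "right"), (10, "left")]))
        assert len(out) == 2 and {o.side for o in out} == {"left", "right"}

    def test_single_origin(self):
        out = order_along_midvein(_origins([(5, "left")]))
        assert len(out) == 1
        assert not any(r.defined for r in compute_ratios(out))


class TestComputeRatios:
    def test_alternate_archetype_r_half(self):
        # a left origin halfway between two right ones: r = 0.5
        recs = compute_ratios(
            _origins([(0, "left"), (1, "right"), (2, "left")]), metric="axial")
        rec = next(r for r in recs if r.s == 0)
        assert (rec.d_opposite, rec.d_same, rec.r) == (1.0, 2.0, 0.5)

    def test_opposite_archetype_r_zero(self):
        recs = compute_ratios(
            _origins([(0, "left"), (0, "right"), (1, "left"), (1, "right")]),
            metric="axial")
        rec = next(r for r in recs if r.s == 0 and r.side == "left")
        assert rec.d_opposite == 0.0 and rec.r == 0.0 and rec.defined

    def test_irregular_same_side_succession(self):
        recs = compute_ratios(
            _origins([(0, "left"), (1, "left"), (3, "right")]), metric="axial")
        rec = next(r for r in recs if r.s == 0)
        assert rec.d_same == 1.0 and rec.d_opposite == 3.0
        assert rec.r == 3.0 and rec.irregular

    def test_r_exactly_one_not_irregular(self):
        recs = compute_ratios(
            _origins([(0, "left"), (1, "right"), (1, "left"), (2, "right")]),
            metric="axial")
        rec = next(r for r in recs if r.s == 0)
        assert rec.r == 1.0 and not rec.irregular

    def test_apical_origins_undefined(self):
        recs = compute_ratios(
            _origins([(0, "left"), (1, "right"), (2, "left")]), metric="axial")
        undefined = [r for r in recs if not r.defined]
        assert {r.s for r in undefined} == {1, 2}

    def test_defined_count_bound(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 30))
            layout = [(float(s), "left" if rng.random() < 0.5 else "right")
                    for s in np.sort(rng.random(n) * 100)]
            recs = compute_ratios(_origins(layout), metric="axial")
            assert sum(r.defined for r in recs) <= n - 2

    def test_duplicate_same_side_position_invalid(self):
        with pytest.warns(UserWarning, match="duplicate same-side"):
            recs = compute_ratios(
                _origins([(0, "left"), (0, "left"), (1, "right"), (2, "left")]),
                metric="axial")
        assert any(not r.defined and r.d_same == 0.0 for r in recs)

    def test_unknown_metric(self):
        with pytest.raises(ValueError):
            compute_ratios(_origins([(0, "left")]), metric="manhattan")


def _similarity(points, angle, scale, shift):
    rot = np.array([[np.cos(angle), -np.sin(angle)],
                    [np.sin(angle), np.cos(angle)]])
    return [tuple(scale * rot @ np.array(p) + shift) for p in points]


class TestRatioInvariances:
    def _leaf(self, coords):
        axis = MidveinAxis(nodes=(coords[0], coords[1]))
        origins = [VeinOrigin(leaf_id="t", x=x, y=y) for x, y in coords[2:]]
        return LeafRecord(leaf_id="t", species="S", axis=axis, origins=origins)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        angle=st.floats(0, 2 * np.pi),
        scale=st.floats(0.2, 5.0),
        dx=st.floats(-50, 50),
        dy=st.floats(-50, 50),
        metric=st.sampled_from(["euclidean", "axial"]),
    )
    def test_similarity_invariance(self, angle, scale, dx, dy, metric):
        # r depends only on relative positions: translation, rotation and
        # uniform scaling leave every defined ratio unchanged
        base = [(0.0, 0.0), (0.0, 100.0),
                (-2.0, 10.0), (3.0, 25.0), (-2.5, 41.0), (2.0, 55.0),
                (-1.5, 70.0), (2.5, 88.0)]
        r0 = [r.r for r in leaf_ratios(self._leaf(base), metric=metric) if r.defined]
        moved = _similarity(base, angle, scale, np.array([dx, dy]))
        r1 = [r.r for r in leaf_ratios(self._leaf(moved), metric=metric) if r.defined]
        assert np.allclose(sorted(r0), sorted(r1), atol=1e-8)

    def test_mirror_invariance_of_ratio_multiset(self):
        base = [(0.0, 0.0), (0.0, 100.0),
                (-2.0, 10.0), (3.0, 25.0), (-2.5, 41.0), (2.0, 55.0),
                (-1.5, 70.0), (2.5, 88.0)]
        mirrored = [(-x, y) for x, y in base]
        r0 = sorted(r.r for r in leaf_ratios(self._leaf(base)) if r.defined)
        r1 = sorted(r.r for r in leaf_ratios(self._leaf(mirrored)) if r.defined)
        assert np.allclose(r0, r1, atol=1e-12)

    def test_euclidean_and_axial_agree_for_small_offsets(self, rng):
        # offsets <= 2% of the internode keep the two metrics within 0.05
        axis = MidveinAxis(nodes=((0.0, 0.0), (0.0, 200.0)))
        ys = np.sort(rng.uniform(5, 195, 14))
        internode = float(np.diff(ys).mean())
        coords = [(0.0, 0.0), (0.0, 200.0)] + [
            ((1 if i % 2 else -1) * 0.02 * internode * rng.random(), y)
            for i, y in enumerate(ys)
        ]
        leaf = self._leaf(coords)
        re = {r.vein_index: r.r for r in leaf_ratios(leaf, metric="euclidean")
              if r.defined}
        ra = {r.vein_index: r.r for r in leaf_ratios(leaf, metric="axial")
              if r.defined}
        for k in re:
            assert abs(re[k] - ra[k]) <= 0.05
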