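"""Geometry of lateral-vein origins along a midvein.

Turns digitized bifurcation-point coordinates into ordered, side-labelled
origins along the midvein axis and computes, for each lateral vein, the
spacing ratio

    r = d_opposite / d_same,

where ``d_opposite`` is the distance from a vein origin to the next origin
on the opposite side of the midvein (apical-or-coincident) and ``d_same``
the distance to the next origin on the same side (strictly apical).  A
value near 0.5 marks an alternate-like arrangement, values near 0 or 1 an
opposite-like one, and r > 1 the irregular pattern of two successive
same-side veins.

Coordinates are in image pixels with y increasing downward (the scanner /
ImageJ convention); every quantity computed here depends only on relative
positions, so the convention never matters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from shapely.geometry import LineString, Point

logger = logging.getLogger(__name__)

__all__ = [
    "MidveinAxis",
    "VeinOrigin",
    "RatioRecord",
    "LeafRecord",
    "axial_position",
    "assign_sides",
    "order_along_midvein",
    "compute_ratios",
    "leaf_ratios",
]


class GeometryError(ValueError):
    """Raised for degenerate geometric input (e.g. a zero-length axis)."""


@dataclass(frozen=True)
class MidveinAxis:
    """Midvein polyline from lamina base to tip, in pixels."""

    nodes: tuple[tuple[float, float], ...]

    def __post_init__(self):
        if len(self.nodes) < 2:
            raise GeometryError("midvein axis needs at least 2 nodes")
        arr = np.asarray(self.nodes, dtype=float)
        seg = np.diff(arr, axis=0)
        lengths = np.hypot(seg[:, 0], seg[:, 1])
        if np.any(lengths == 0.0):
            raise GeometryError("consecutive axis nodes must be distinct")

    @property
    def line(self) -> LineString:
        return LineString(self.nodes)

    @property
    def length(self) -> float:
        return float(self.line.length)


@dataclass
class VeinOrigin:
    """A lateral-vein bifurcation point on the midvein.

    ``s`` is the arc-length position of its projection onto the axis
    (pixels from the lamina base); ``side`` is 'left' or 'right' as seen
    along the base-to-tip direction.
    """

    leaf_id: str
    x: float
    y: float
    s: float = float("nan")
    side: str | None = None
    index: int = -1


@dataclass(frozen=True)
class RatioRecord:
    """Per-vein spacing ratio r = d_opposite / d_same."""

    leaf_id: str
    vein_index: int
    side: str
    s: float
    d_opposite: float
    d_same: float
    r: float
    defined: bool
    irregular: bool


@dataclass
class LeafRecord:
    """One leaf or leaflet: identity, midvein axis and its vein origins.

    ``leaflet_position`` is 'simple' for simple leaves, or
    'terminal' / 'left' / 'right' for leaflets of a compound leaf;
    ``compound_leaf_id`` groups the leaflets of one compound leaf.
    """

    leaf_id: str
    species: str
    axis: MidveinAxis
    origins: list[VeinOrigin] = field(default_factory=list)
    leaflet_position: str = "simple"
    compound_leaf_id: str | None = None


# ---------------------------------------------------------------------------
# projection onto the axis
# ---------------------------------------------------------------------------

def axial_position(axis: MidveinAxis, point: tuple[float, float]) -> float:
    """Arc length from the lamina base to the projection of ``point``.

    The point is projected orthogonally onto the nearest axis segment;
    the result lies in [0, axis.length].
    """
    return float(axis.line.project(Point(point)))


def _local_tangent_and_offset(axis: MidveinAxis, point: tuple[float, float]):
    """Tangent of the nearest axis segment and the offset vector to the point."""
    line = axis.line
    p = Point(point)
    s = line.project(p)
    foot = line.interpolate(s)
    nodes = np.asarray(axis.nodes, dtype=float)
    seg_len = np.hypot(*np.diff(nodes, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    # segment containing s (the final segment for s == total length)
    i = int(np.searchsorted(cum, s, side="right") - 1)
    i = min(max(i, 0), len(seg_len) - 1)
    tangent = nodes[i + 1] - nodes[i]
    offset = np.array([point[0] - foot.x, point[1] - foot.y])
    return tangent, offset


def assign_sides(axis: MidveinAxis, origins: list[VeinOrigin]) -> list[VeinOrigin]:
    """Label each origin 'left' or 'right' of the base-to-tip axis.

    The side is the sign of the cross product of the local axis tangent
    with the offset vector from the projection foot to the point.  Origins
    lying exactly on the axis cannot be sided; they are excluded with a
    warning.  Labels are consistent within a leaf; mirroring the leaf
    swaps every label.
    """
    out: list[VeinOrigin] = []
    for o in origins:
        tangent, offset = _local_tangent_and_offset(axis, (o.x, o.y))
        cross = tangent[0] * offset[1] - tangent[1] * offset[0]
        if cross == 0.0:
            warnings.warn(
                f"origin at ({o.x}, {o.y}) of leaf {o.leaf_id!r} lies on the "
                "midvein axis; excluded from side assignment"
            )
            continue
        o.side = "left" if cross > 0 else "right"
        o.s = axial_position(axis, (o.x, o.y))
        out.append(o)
    return out


def order_along_midvein(origins: list[VeinOrigin]) -> list[VeinOrigin]:
    """Sort origins by axial position, reassigning indices 0..n-1.

    Ties in ``s`` (e.g. an exactly opposite pair) are kept, ordered
    deterministically by (side, input order).
    """
    keyed = sorted(
        enumerate(origins),
        key=lambda t: (t[1].s, t[1].side or "", t[0]),
    )
    ordered = [o for _, o in keyed]
    for i, o in enumerate(ordered):
        o.index = i
    return ordered


# ---------------------------------------------------------------------------
# the spacing ratio
# ---------------------------------------------------------------------------

def _distance(a: VeinOrigin, b: VeinOrigin, metric: str) -> float:
    if metric == "axial":
        return abs(b.s - a.s)
    return float(np.hypot(b.x - a.x, b.y - a.y))


def compute_ratios(origins: list[VeinOrigin], metric: str = "euclidean") -> list[RatioRecord]:
    """Spacing ratio r = d_opposite / d_same for each ordered origin.

    For an origin at axial position s on side sigma, the same-side
    neighbour is the nearest origin with side sigma strictly apical
    (s' > s) and the opposite-side neighbour the nearest with the other
    side, apical or coincident (s' >= s) - so an exactly opposite partner
    yields d_opposite = 0 and r = 0.  Distances are euclidean between the
    two bifurcation points, or axial (|s' - s|) when ``metric='axial'``.
    Origins lacking either neighbour (the apical boundary) are returned
    with ``defined=False`` rather than imputed; r = 1 is not irregular,
    irregular is strictly r > 1, and extreme values are never capped.
    """
    if metric not in ("euclidean", "axial"):
        raise ValueError(f"unknown metric {metric!r}")
    ordered = sorted(enumerate(origins), key=lambda t: (t[1].s, t[0]))
    records: list[RatioRecord] = []
    n = len(ordered)
    for pos, (_, o) in enumerate(ordered):
        if o.side is None:
            continue
        if any(c is not o and c.side == o.side and c.s == o.s
               for _, c in ordered):
            warnings.warn(
                f"duplicate same-side position at s={o.s} in leaf "
                f"{o.leaf_id!r}; ratio undefined"
            )
            records.append(RatioRecord(
                leaf_id=o.leaf_id, vein_index=o.index, side=o.side, s=o.s,
                d_opposite=float("nan"), d_same=0.0, r=float("nan"),
                defined=False, irregular=False,
            ))
            continue
        same = None
        opposite = None
        for _, cand in (ordered[q] for q in range(pos + 1, n)):
            if cand.side == o.side:
                if same is None and cand.s > o.s:
                    same = cand
            elif opposite is None:
                opposite = cand  # s' >= s holds by ordering
            if same is not None and opposite is not None:
                break
        # an exactly coincident opposite partner may sort before this origin
        if opposite is None or any(
            c.side != o.side and c.s == o.s for _, c in ordered[:pos]
        ):
            for _, cand in (ordered[q] for q in range(pos)):
                if cand.side != o.side and cand.s == o.s:
                    opposite = cand
                    break
        if same is None or opposite is None:
            records.append(RatioRecord(
                leaf_id=o.leaf_id, vein_index=o.index, side=o.side, s=o.s,
                d_opposite=float("nan"), d_same=float("nan"), r=float("nan"),
                defined=False, irregular=False,
            ))
            continue
        d_same = _distance(o, same, metric)
        d_opp = _distance(o, opposite, metric)
        if d_same == 0.0:
            warnings.warn(
                f"duplicate same-side position at s={o.s} in leaf "
                f"{o.leaf_id!r}; ratio undefined"
            )
            records.append(RatioRecord(
                leaf_id=o.leaf_id, vein_index=o.index, side=o.side, s=o.s,
                d_opposite=d_opp, d_same=0.0, r=float("nan"),
                defined=False, irregular=False,
            ))
            continue
        r = d_opp / d_same
        records.append(RatioRecord(
            leaf_id=o.leaf_id, vein_index=o.index, side=o.side, s=o.s,
            d_opposite=d_opp, d_same=d_same, r=r,
            defined=True, irregular=bool(r > 1.0),
        ))
    return records


def leaf_ratios(leaf: LeafRecord, metric: str = "euclidean") -> list[RatioRecord]:
    """Full per-leaf pipeline: project, side, order, then ratio."""
    origins = assign_sides(leaf.axis, list(leaf.origins))
    origins = order_along_midvein(origins)
    return compute_ratios(origins, metric=metric)
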