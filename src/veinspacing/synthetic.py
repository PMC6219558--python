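"""Synthetic vein-origin arrangements.

Generates coordinate sets with the statistical structure the analysis
assumes, spanning the continuum of archetypes:

* ``phase`` (delta in [0, 0.5]) is the axial offset of each right-side
  origin as a fraction of its local internode: 0.5 places right origins
  halfway between left ones (ideal alternate, every r = 0.5), 0 places
  them coincident (ideal opposite, r modes at 0 and 1);
* internodes are truncated-normal with a stated mean and coefficient of
  variation (redrawn until positive) - a minimal two-parameter stand-in,
  since no spacing distribution is implied by real leaves;
* ``jitter_sd`` adds independent axial noise (fraction of the mean
  internode) to every origin;
* with probability ``irregular_prob`` per vein an extra origin is
  inserted on the same side midway to the next same-side origin,
  reproducing the irregular two-successive-veins pattern (r > 1); a
  deletion variant removes the opposite partner instead.

Same seed, same parameters -> bit-identical output.  Everything real
leaves have beyond this model (curved midveins, basal/apical crowding,
digitization error correlated along the leaf) is deliberately absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import LeafRecord, MidveinAxis, VeinOrigin, compute_ratios
from .io import PointAnnotation

__all__ = [
    "SyntheticParams",
    "SyntheticLeaf",
    "generate_arrangement",
    "generate_compound_leaf",
    "leaf_to_points",
]


@dataclass(frozen=True)
class SyntheticParams:
    """Generative knobs for one synthetic leaf.

    Units are pixels (arbitrary); defaults give ~1% lateral offset so the
    euclidean and axial ratio metrics nearly coincide.
    """

    n_pairs: int = 15
    internode_mean: float = 30.0
    internode_cv: float = 0.15
    phase: float = 0.5
    jitter_sd: float = 0.0
    irregular_prob: float = 0.0
    lateral_offset: float = 0.3
    irregular_mode: str = "insert"
    seed: int = 0

    def __post_init__(self):
        if self.n_pairs < 2:
            raise ValueError("n_pairs must be >= 2")
        if self.internode_mean <= 0:
            raise ValueError("internode_mean must be > 0")
        if not 0.0 <= self.phase <= 0.5:
            raise ValueError("phase must lie in [0, 0.5]")
        if not 0.0 <= self.irregular_prob < 1.0:
            raise ValueError("irregular_prob must lie in [0, 1)")
        if self.jitter_sd < 0 or self.internode_cv < 0:
            raise ValueError("jitter_sd and internode_cv must be >= 0")
        if self.lateral_offset <= 0:
            raise ValueError("lateral_offset must be > 0 (origins on the axis cannot be sided)")
        if self.irregular_mode not in ("insert", "delete"):
            raise ValueError(f"unknown irregular_mode {self.irregular_mode!r}")


@dataclass
class SyntheticLeaf:
    """A generated leaf plus its ground truth."""

    leaf: LeafRecord
    params: SyntheticParams
    true_r: tuple[float, ...]
    irregular_insertions: tuple[tuple[str, float], ...]  # (side, relative position)

    @property
    def axis_length(self) -> float:
        return self.leaf.axis.length


def _positive_normal(rng, mean, sd, size):
    """Normal draws resampled until strictly positive."""
    out = rng.normal(mean, sd, size) if sd > 0 else np.full(size, float(mean))
    while True:
        bad = out <= 0
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, int(bad.sum()))


def _noiseless_positions(params: SyntheticParams, internodes: np.ndarray):
    s0 = params.internode_mean  # basal margin
    left = s0 + np.concatenate([[0.0], np.cumsum(internodes[:-1])])
    right = left + params.phase * internodes
    return left, right


def _true_ratios(params: SyntheticParams, left: np.ndarray, right: np.ndarray):
    origins = (
        [VeinOrigin(leaf_id="", x=-1.0, y=s, s=s, side="left") for s in left]
        + [VeinOrigin(leaf_id="", x=1.0, y=s, s=s, side="right") for s in right]
    )
    recs = compute_ratios(origins, metric="axial")
    return tuple(rec.r for rec in recs if rec.defined)


def generate_arrangement(
    params: SyntheticParams,
    rng: np.random.Generator | None = None,
    leaf_id: str = "synthetic",
    species: str = "SYN",
    leaflet_position: str = "simple",
    compound_leaf_id: str | None = None,
    forced_insertions: tuple[tuple[str, float], ...] | None = None,
) -> SyntheticLeaf:
    """Generate one leaf along a straight vertical midvein.

    ``forced_insertions`` overrides the stochastic irregular draws with
    explicit (side, relative position) insertions - the hook used for
    mirrored leaflet pairs.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = params.n_pairs
    internodes = _positive_normal(
        rng, params.internode_mean, params.internode_cv * params.internode_mean, n
    )
    left, right = _noiseless_positions(params, internodes)
    true_r = _true_ratios(params, left, right)

    if params.jitter_sd > 0:
        jsd = params.jitter_sd * params.internode_mean
        left = left + rng.normal(0.0, jsd, n)
        right = right + rng.normal(0.0, jsd, n)

    sides = {"left": np.sort(left), "right": np.sort(right)}
    tip = max(sides["left"][-1], sides["right"][-1]) + params.internode_mean
    base_margin = min(sides["left"][0], sides["right"][0])
    if base_margin <= 0:
        shift = params.internode_mean - base_margin
        sides = {k: v + shift for k, v in sides.items()}
        tip += shift
    length = float(tip)

    insertions: list[tuple[str, float]] = []
    if forced_insertions is not None:
        for side, rel in forced_insertions:
            sides[side] = np.sort(np.append(sides[side], rel * length))
            insertions.append((side, rel))
    elif params.irregular_prob > 0:
        if params.irregular_mode == "insert":
            for side in ("left", "right"):
                s = sides[side]
                extra = []
                for i in range(len(s) - 1):
                    if rng.random() < params.irregular_prob:
                        pos = 0.5 * (s[i] + s[i + 1])
                        extra.append(pos)
                        insertions.append((side, pos / length))
                if extra:
                    sides[side] = np.sort(np.concatenate([s, extra]))
        else:  # delete the opposite partner, leaving a same-side succession
            for side in ("left", "right"):
                s = sides[side]
                keep = rng.random(len(s)) >= params.irregular_prob
                for pos in s[~keep]:
                    insertions.append((side, pos / length))
                if keep.sum() >= 2:
                    sides[side] = s[keep]

    axis = MidveinAxis(nodes=((0.0, 0.0), (0.0, length)))
    origins = [
        VeinOrigin(leaf_id=leaf_id, x=-params.lateral_offset, y=float(s))
        for s in sides["left"]
    ] + [
        VeinOrigin(leaf_id=leaf_id, x=+params.lateral_offset, y=float(s))
        for s in sides["right"]
    ]
    leaf = LeafRecord(
        leaf_id=leaf_id, species=species, axis=axis, origins=origins,
        leaflet_position=leaflet_position, compound_leaf_id=compound_leaf_id,
    )
    return SyntheticLeaf(
        leaf=leaf, params=params, true_r=true_r,
        irregular_insertions=tuple(insertions),
    )


def generate_compound_leaf(
    params: SyntheticParams,
    mirrored_irregulars: bool = False,
    rng: np.random.Generator | None = None,
    compound_leaf_id: str = "compound",
    species: str = "SYN",
) -> tuple[SyntheticLeaf, SyntheticLeaf, SyntheticLeaf]:
    """Three leaflets (terminal, left, right) of a ternate compound leaf.

    Leaflets are drawn independently, except that with
    ``mirrored_irregulars=True`` the right-positioned leaflet receives its
    irregular insertions at the same relative positions as the
    left-positioned one, on the mirrored side - the systematic-rule
    scenario that the leaflet-pair symmetry analysis should recognize.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    terminal = generate_arrangement(
        params, rng=rng, leaf_id=f"{compound_leaf_id}_T", species=species,
        leaflet_position="terminal", compound_leaf_id=compound_leaf_id,
    )
    left = generate_arrangement(
        params, rng=rng, leaf_id=f"{compound_leaf_id}_L", species=species,
        leaflet_position="left", compound_leaf_id=compound_leaf_id,
    )
    if mirrored_irregulars:
        mirrored = tuple(
            ("right" if side == "left" else "left", rel)
            for side, rel in left.irregular_insertions
        )
        right = generate_arrangement(
            replace(params, irregular_prob=0.0), rng=rng,
            leaf_id=f"{compound_leaf_id}_R", species=species,
            leaflet_position="right", compound_leaf_id=compound_leaf_id,
            forced_insertions=mirrored,
        )
    else:
        right = generate_arrangement(
            params, rng=rng, leaf_id=f"{compound_leaf_id}_R", species=species,
            leaflet_position="right", compound_leaf_id=compound_leaf_id,
        )
    return terminal, left, right


def leaf_to_points(synth: SyntheticLeaf | LeafRecord) -> list[PointAnnotation]:
    """Express a leaf in the role-annotated point dialect the io module reads."""
    leaf = synth.leaf if isinstance(synth, SyntheticLeaf) else synth
    nodes = leaf.axis.nodes
    points = [PointAnnotation(leaf_id=leaf.leaf_id, x=nodes[0][0], y=nodes[0][1],
                              role="midvein_base")]
    for x, y in nodes[1:-1]:
        points.append(PointAnnotation(leaf_id=leaf.leaf_id, x=x, y=y, role="midvein_node"))
    points.append(PointAnnotation(leaf_id=leaf.leaf_id, x=nodes[-1][0], y=nodes[-1][1],
                                  role="midvein_tip"))
    for o in leaf.origins:
        points.append(PointAnnotation(leaf_id=leaf.leaf_id, x=o.x, y=o.y,
                                      role="vein_origin"))
    return points
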