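"""Species-level pooling, group comparison and leaflet-pair symmetry.

The pipeline's top layer mirrors the study design it implements:

* per species, all defined r values are pooled across leaves/leaflets and
  the pooled distribution is scored for departure from unimodality with
  the dip test (a small p-value = departure from the alternate-like
  archetype) and summarized as a violin density;
* the species-level dip p-values are compared between groups (stem-level
  phyllotaxis alternate vs. opposite, or life form woody vs. herbaceous)
  with the two-sided Brunner-Munzel test;
* irregular cases (r > 1) on the left/right leaflets of ternate compound
  leaves are mapped to a signed coordinate (left-leaflet tip = -1, bases
  = 0, right-leaflet tip = +1) and checked for mirror-image placement.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import LeafRecord, MidveinAxis, RatioRecord, VeinOrigin, leaf_ratios
from .io import SpeciesMeta
from .stats import (
    BMResult,
    DensitySummary,
    DipResult,
    brunner_munzel,
    density_summary,
    dip_test,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SpeciesResult",
    "PairSymmetryRecord",
    "analyze_species",
    "compare_groups",
    "relative_position",
    "leaflet_pair_analysis",
]

LEAFLET_FILTERS = ("all", "terminal", "left", "right")


@dataclass
class SpeciesResult:
    """Pooled per-species outcome of the ratio analysis."""

    code: str
    n_leaves: int
    n_veins: int
    r_values: np.ndarray
    dip: DipResult | None
    density: DensitySummary | None
    n_irregular: int
    empty: bool = False

    def to_row(self) -> dict:
        row = {
            "code": self.code, "n_leaves": self.n_leaves,
            "n_veins": self.n_veins, "n_irregular": self.n_irregular,
        }
        if self.dip is not None:
            row.update(dip=self.dip.dip, dip_p=self.dip.p_value,
                       dip_reps=self.dip.reps, dip_seed=self.dip.seed)
        if self.density is not None:
            row.update(bandwidth=self.density.bandwidth,
                       n_modes=len(self.density.modes))
        return row


@dataclass(frozen=True)
class PairSymmetryRecord:
    """One irregular case on a left/right leaflet pair.

    ``paired_coordinate`` maps the case to [-1, 1]: minus the relative
    position on the left-positioned leaflet, plus it on the right one, so
    that both bases sit at 0 and the tips at -1 and +1.
    """

    compound_leaf_id: str
    side: str  # 'left_leaflet' or 'right_leaflet'
    r: float
    position: float
    paired_coordinate: float
    mirror_matched: bool


def analyze_species(
    leaves: list[LeafRecord],
    meta: SpeciesMeta | None = None,
    leaflet_filter: str = "all",
    metric: str = "euclidean",
    dip_reps: int = 10_000,
    seed: int = 0,
    truncate_at: float | None = None,
) -> SpeciesResult:
    """Pool the ratios of one species and score the pooled distribution.

    ``leaflet_filter`` reproduces the per-position design for compound
    leaves ('terminal', 'left', 'right', or 'all'; simple leaves pass
    every filter set to 'all').  The dip test is run on the full pool,
    including r > 1; ``truncate_at`` optionally restricts the pool (the
    display variant some figures use, e.g. r <= 1.5).
    """
    if leaflet_filter not in LEAFLET_FILTERS:
        raise ValueError(f"leaflet_filter must be one of {LEAFLET_FILTERS}")
    code = meta.code if meta is not None else (leaves[0].species if leaves else "")
    if leaflet_filter == "all":
        kept = list(leaves)
    else:
        kept = [lf for lf in leaves if lf.leaflet_position == leaflet_filter]
    pooled: list[float] = []
    n_leaves = 0
    for leaf in kept:
        recs = leaf_ratios(leaf, metric=metric)
        n_leaves += 1
        pooled.extend(rec.r for rec in recs if rec.defined)
    r = np.asarray(pooled, dtype=float)
    if truncate_at is not None:
        r = r[r <= truncate_at]
    if r.size == 0:
        logger.warning("species %s: empty ratio pool after filtering", code)
        return SpeciesResult(code=code, n_leaves=n_leaves, n_veins=0,
                             r_values=r, dip=None, density=None,
                             n_irregular=0, empty=True)
    dip = dip_test(r, reps=dip_reps, seed=seed) if r.size >= 2 else None
    density = density_summary(r) if r.size >= 1 else None
    return SpeciesResult(
        code=code, n_leaves=n_leaves, n_veins=int(r.size), r_values=r,
        dip=dip, density=density, n_irregular=int(np.sum(r > 1.0)),
    )


def compare_groups(
    results: list[SpeciesResult],
    meta: list[SpeciesMeta],
    grouping: str = "phyllotaxis",
) -> dict:
    """Brunner-Munzel comparison of species dip p-values between groups.

    One dip p-value per species enters the test; groups are the two
    levels of ``grouping`` ('phyllotaxis': alternate vs. opposite,
    'life_form': woody vs. herbaceous).
    """
    if grouping not in ("phyllotaxis", "life_form"):
        raise ValueError(f"unknown grouping {grouping!r}")
    by_code = {m.code: m for m in meta}
    levels: dict[str, list[float]] = {}
    for res in results:
        if res.empty or res.dip is None:
            continue
        m = by_code.get(res.code)
        if m is None:
            raise ValueError(f"species {res.code!r} missing from the metadata table")
        levels.setdefault(getattr(m, grouping), []).append(res.dip.p_value)
    if len(levels) != 2:
        raise ValueError(
            f"grouping {grouping!r} must have exactly 2 levels with data, "
            f"got {sorted(levels)}"
        )
    (name_x, x), (name_y, y) = sorted(levels.items())
    if len(x) < 2 or len(y) < 2:
        raise ValueError(
            f"each group needs >= 2 species: {name_x}={len(x)}, {name_y}={len(y)}"
        )
    bm = brunner_munzel(x, y)
    return {"grouping": grouping, "groups": (name_x, name_y),
            "sizes": (len(x), len(y)), "result": bm}


def relative_position(origin: VeinOrigin | tuple[float, float],
                      axis: MidveinAxis) -> float:
    """Axial position scaled by leaflet length: 0 = base, 1 = tip."""
    length = axis.length
    if length <= 0:
        raise ValueError("zero-length axis")
    if isinstance(origin, VeinOrigin):
        from .geometry import axial_position
        s = axial_position(axis, (origin.x, origin.y)) if np.isnan(origin.s) else origin.s
    else:
        from .geometry import axial_position
        s = axial_position(axis, origin)
    return float(s / length)


def leaflet_pair_analysis(
    leaves: list[LeafRecord],
    tolerance: float = 0.1,
    metric: str = "euclidean",
) -> tuple[list[PairSymmetryRecord], dict[str, str]]:
    """Mirror-image check of irregular (r > 1) cases on leaflet pairs.

    For every compound leaf supplying a left- and a right-positioned
    leaflet, each irregular case is mapped to the signed [-1, 1]
    coordinate and flagged ``mirror_matched`` when the opposite leaflet
    shows an irregular case within ``tolerance`` (fraction of leaflet
    length) of the same relative position.  The per-pair verdict is
    'mirror' only if both leaflets have irregular cases and every one of
    them is matched; pairs without any irregular case are excluded.
    Terminal leaflets never enter the pairing.
    """
    groups: dict[str, dict[str, LeafRecord]] = {}
    for leaf in leaves:
        if leaf.compound_leaf_id is None or leaf.leaflet_position not in ("left", "right"):
            continue
        groups.setdefault(leaf.compound_leaf_id, {})[leaf.leaflet_position] = leaf

    records: list[PairSymmetryRecord] = []
    verdicts: dict[str, str] = {}
    for cid, pair in sorted(groups.items()):
        if set(pair) != {"left", "right"}:
            warnings.warn(f"compound leaf {cid!r}: unpaired leaflet, skipped")
            continue
        cases = {"left": [], "right": []}
        for pos in ("left", "right"):
            leaf = pair[pos]
            length = leaf.axis.length
            for rec in leaf_ratios(leaf, metric=metric):
                if rec.defined and rec.irregular:
                    cases[pos].append((rec.s / length, rec.r))
        if not cases["left"] and not cases["right"]:
            continue
        all_matched = True
        for pos, other in (("left", "right"), ("right", "left")):
            sign = -1.0 if pos == "left" else 1.0
            for rel, r in cases[pos]:
                matched = any(abs(rel - rel2) <= tolerance for rel2, _ in cases[other])
                all_matched &= matched
                records.append(PairSymmetryRecord(
                    compound_leaf_id=cid, side=f"{pos}_leaflet", r=r,
                    position=rel, paired_coordinate=sign * rel,
                    mirror_matched=matched,
                ))
        both = bool(cases["left"]) and bool(cases["right"])
        verdicts[cid] = "mirror" if (both and all_matched) else "not mirror"
    return records, verdicts
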