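"""Reading digitized coordinates and species metadata; writing result tables.

Two coordinate dialects are supported:

* plain two-column XY text, as exported by the ImageJ point tool: one
  point per line, whitespace- or comma-delimited, optional header.  Files
  in this dialect carry no role labels, so a block convention applies:
  the leading axis block (first point = midvein base, last point of the
  block = midvein tip, any points between = midvein nodes) followed by
  the vein origins;
* a richer CSV with explicit columns ``leaf_id, role, x, y``, where role
  is one of ``midvein_base``, ``midvein_tip``, ``midvein_node``,
  ``vein_origin``.  This is the preferred format and the one the
  synthetic generator writes.

Species metadata is a CSV keyed by the 3-letter species code, carrying the
grouping variables used downstream (stem-level phyllotaxis alternate /
opposite; life form woody / herbaceous) plus pass-through descriptors.  A
bundled table covers the 30 temperate dicot species of the reference
dataset (18 alternate + 12 opposite, 18 woody + 12 herbaceous).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, fields as dc_fields
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import LeafRecord, MidveinAxis, VeinOrigin

logger = logging.getLogger(__name__)

__all__ = [
    "SpeciesMeta",
    "PointAnnotation",
    "read_imagej_xy",
    "read_point_csv",
    "read_species_metadata",
    "load_species_table",
    "points_to_leaf",
    "write_results",
    "read_results",
]

ROLES = ("vein_origin", "midvein_base", "midvein_tip", "midvein_node")
PHYLLOTAXIS_LEVELS = ("alternate", "opposite")
LIFE_FORM_LEVELS = ("woody", "herbaceous")
LEAF_TYPES = ("simple", "pinnate", "ternate", "palmate")


@dataclass(frozen=True)
class SpeciesMeta:
    code: str
    phyllotaxis: str
    life_form: str
    binomial: str = ""
    family: str = ""
    leaf_type: str = "simple"
    venation_class: str = ""

    def __post_init__(self):
        if self.phyllotaxis not in PHYLLOTAXIS_LEVELS:
            raise ValueError(
                f"species {self.code!r}: phyllotaxis must be one of "
                f"{PHYLLOTAXIS_LEVELS}, got {self.phyllotaxis!r}"
            )
        if self.life_form not in LIFE_FORM_LEVELS:
            raise ValueError(
                f"species {self.code!r}: life_form must be one of "
                f"{LIFE_FORM_LEVELS}, got {self.life_form!r}"
            )


@dataclass(frozen=True)
class PointAnnotation:
    """A digitized point: a vein origin or a midvein axis landmark."""

    leaf_id: str
    x: float
    y: float
    role: str

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"unknown point role {self.role!r}")


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# coordinate readers
# ---------------------------------------------------------------------------

def _parse_xy_line(line: str, lineno: int, path) -> tuple[float, float]:
    parts = line.replace(",", " ").split()
    if len(parts) < 2:
        raise ParseError(f"{path}:{lineno}: expected at least 2 columns, got {len(parts)}")
    try:
        return float(parts[0]), float(parts[1])
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: non-numeric row {line.strip()!r}") from exc


def read_imagej_xy(path, leaf_id: str | None = None, n_axis: int = 2) -> list[PointAnnotation]:
    """Read a plain two-column XY export (ImageJ point-tool style).

    The first ``n_axis`` points are the midvein axis block (first =
    midvein_base, last = midvein_tip, intermediates = midvein_node); the
    remaining points are vein origins.  A single non-numeric header line
    is tolerated and skipped.

    Parameters
    ----------
    path : path-like
    leaf_id : str, optional
        Defaults to the file stem.
    n_axis : int
        Number of leading axis points (>= 2).
    """
    path = Path(path)
    if leaf_id is None:
        leaf_id = path.stem
    if n_axis < 2:
        raise ValueError("n_axis must be >= 2")
    raw: list[tuple[float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                raw.append(_parse_xy_line(line, lineno, path))
            except ParseError:
                if lineno == 1:  # header
                    continue
                raise
    if not raw:
        logger.warning("empty coordinate file %s", path)
        return []
    points: list[PointAnnotation] = []
    for i, (x, y) in enumerate(raw):
        if i == 0:
            role = "midvein_base"
        elif i == n_axis - 1:
            role = "midvein_tip"
        elif i < n_axis - 1:
            role = "midvein_node"
        else:
            role = "vein_origin"
        points.append(PointAnnotation(leaf_id=leaf_id, x=x, y=y, role=role))
    return points


def read_point_csv(path) -> list[PointAnnotation]:
    """Read the role-annotated CSV dialect (columns leaf_id, role, x, y)."""
    df = pd.read_csv(path)
    required = {"leaf_id", "role", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return [
        PointAnnotation(leaf_id=str(row.leaf_id), x=float(row.x), y=float(row.y),
                        role=str(row.role))
        for row in df.itertuples()
    ]


def points_to_leaf(points: list[PointAnnotation], species: str = "",
                   leaflet_position: str = "simple",
                   compound_leaf_id: str | None = None) -> LeafRecord:
    """Assemble the annotations of one leaf into a LeafRecord.

    Requires exactly one midvein_base and one midvein_tip; midvein_node
    points are threaded between them in file order.
    """
    if not points:
        raise ParseError("no points for leaf")
    leaf_ids = {p.leaf_id for p in points}
    if len(leaf_ids) != 1:
        raise ParseError(f"points span multiple leaf_ids: {sorted(leaf_ids)}")
    leaf_id = points[0].leaf_id
    base = [p for p in points if p.role == "midvein_base"]
    tip = [p for p in points if p.role == "midvein_tip"]
    if len(base) != 1 or len(tip) != 1:
        raise ParseError(
            f"leaf {leaf_id!r}: need exactly one midvein_base and one "
            f"midvein_tip, got {len(base)} and {len(tip)}"
        )
    nodes = ([(base[0].x, base[0].y)]
             + [(p.x, p.y) for p in points if p.role == "midvein_node"]
             + [(tip[0].x, tip[0].y)])
    axis = MidveinAxis(nodes=tuple(nodes))
    origins = [VeinOrigin(leaf_id=leaf_id, x=p.x, y=p.y)
               for p in points if p.role == "vein_origin"]
    return LeafRecord(leaf_id=leaf_id, species=species, axis=axis,
                      origins=origins, leaflet_position=leaflet_position,
                      compound_leaf_id=compound_leaf_id)


# ---------------------------------------------------------------------------
# species metadata
# ---------------------------------------------------------------------------

def read_species_metadata(path) -> list[SpeciesMeta]:
    """Read a species metadata CSV (required: code, phyllotaxis, life_form)."""
    df = pd.read_csv(path).fillna("")
    required = {"code", "phyllotaxis", "life_form"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    errors = []
    metas = []
    for i, row in df.iterrows():
        try:
            metas.append(SpeciesMeta(
                code=str(row["code"]),
                phyllotaxis=str(row["phyllotaxis"]),
                life_form=str(row["life_form"]),
                binomial=str(row.get("binomial", "")),
                family=str(row.get("family", "")),
                leaf_type=str(row.get("leaf_type", "simple")),
                venation_class=str(row.get("venation_class", "")),
            ))
        except ValueError as exc:
            errors.append(f"row {i}: {exc}")
    if errors:
        raise ParseError(f"{path}: invalid metadata rows:\n" + "\n".join(errors))
    codes = [m.code for m in metas]
    if len(set(codes)) != len(codes):
        dupes = sorted({c for c in codes if codes.count(c) > 1})
        raise ParseError(f"{path}: duplicate species codes {dupes}")
    return metas


def load_species_table() -> list[SpeciesMeta]:
    """The bundled 30-species metadata table."""
    ref = resources.files("veinspacing.data") / "species_metadata.csv"
    with resources.as_file(ref) as path:
        return read_species_metadata(path)


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def _to_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    rows = []
    for rec in records:
        if hasattr(rec, "to_row"):
            rows.append(rec.to_row())
        elif hasattr(rec, "__dataclass_fields__"):
            # tabulate scalar fields; nested/array fields have their own outputs
            rows.append({f.name: getattr(rec, f.name) for f in dc_fields(rec)
                         if np.isscalar(getattr(rec, f.name))
                         or getattr(rec, f.name) is None})
        elif isinstance(rec, dict):
            rows.append(rec)
        else:
            raise TypeError(f"cannot tabulate record of type {type(rec)}")
    return pd.DataFrame(rows)


def write_results(records, path, format: str = "csv", allow_empty: bool = False):
    """Write a result table as tidy CSV or JSON.

    Floats are written with 12 significant digits so that reading the file
    back reproduces the table to <= 1e-9 relative error.
    """
    df = _to_frame(records)
    if df.empty and not allow_empty:
        raise ValueError("refusing to write an empty table (pass allow_empty=True)")
    path = Path(path)
    if format == "csv":
        df.to_csv(path, index=False, float_format="%.12g")
    elif format == "json":
        records_out = json.loads(df.to_json(orient="records", double_precision=12))
        with open(path, "w") as fh:
            json.dump(records_out, fh, indent=1)
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def read_results(path, format: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if format is None:
        format = "json" if path.suffix == ".json" else "csv"
    if format == "csv":
        return pd.read_csv(path)
    return pd.DataFrame(json.load(open(path)))
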