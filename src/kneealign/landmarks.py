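"""Landmark data model for AP knee radiographs.

A radiograph is annotated with an ordered set of 2D points outlining the
distal femur and the proximal tibia/fibula (plus the implant outlines on
post-operative images).  Four fixed schemas are supported:

==============  ========  =============================================
schema id       n_points  content
==============  ========  =============================================
pre_original    110       pre-operative knee, short shaft coverage
pre_extended    134       pre_original + 24 extra shaft points
post_original   157       post-operative knee incl. implant outlines
post_extended   181       post_original + 24 extra shaft points
==============  ========  =============================================

Each schema carries a *role table* mapping anatomical roles (femoral/tibial
shaft centre pairs, femoral notch, tibial spine groove / plateau centre,
fibula) to landmark indices.  Point indices are 0-based.  Pixel convention:
origin at the top-left corner, x grows rightward, y grows downward.

All measurement code assumes left-knee orientation (right knees are
horizontally flipped first, mirroring routine practice of normalising
laterality before analysis).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Mapping

import numpy as np

__all__ = [
    "SchemaId",
    "LandmarkSchema",
    "LandmarkSet",
    "SCHEMAS",
    "get_schema",
    "read_pts",
    "write_pts",
    "flip_horizontal",
    "validate",
    "PtsFormatError",
]

COINCIDENT_TOL_PX = 1e-6


class SchemaId(str, Enum):
    """The four supported landmark schemas."""

    PRE_ORIGINAL = "pre_original"
    PRE_EXTENDED = "pre_extended"
    POST_ORIGINAL = "post_original"
    POST_EXTENDED = "post_extended"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def _as_schema_id(schema_id: "SchemaId | str") -> SchemaId:
    if isinstance(schema_id, SchemaId):
        return schema_id
    try:
        return SchemaId(schema_id)
    except ValueError:
        valid = ", ".join(s.value for s in SchemaId)
        raise ValueError(f"unknown schema {schema_id!r}; valid: {valid}") from None


@dataclass(frozen=True)
class LandmarkSchema:
    """A named landmark schema: point count plus anatomical role table.

    Roles map to tuples of indices: axis-defining roles are index *pairs*
    whose midpoint lies on the bone axis; ``tibial_spine_groove`` is a
    single index; ``fibula_indices`` lists every fibula landmark (used for
    automatic lateral-side detection).
    """

    schema_id: SchemaId
    n_points: int
    roles: Mapping[str, tuple[int, ...]]

    def __post_init__(self) -> None:
        for role, idx in self.roles.items():
            if any(i < 0 or i >= self.n_points for i in idx):
                raise ValueError(f"role {role} index out of range for {self.schema_id}")

    @property
    def is_postop(self) -> bool:
        return self.schema_id in (SchemaId.POST_ORIGINAL, SchemaId.POST_EXTENDED)

    def role(self, name: str) -> tuple[int, ...]:
        try:
            return self.roles[name]
        except KeyError:
            raise KeyError(f"schema {self.schema_id} has no role {name!r}") from None


def _schema(schema_id: SchemaId, n: int, **roles: tuple[int, ...]) -> LandmarkSchema:
    return LandmarkSchema(schema_id=schema_id, n_points=n, roles=roles)


#: Registry of the four supported schemas.  Axis-defining index pairs follow
#: the published measurement recipes; fibula index blocks are part of the
#: synthetic template layout (any block of fibula outline points works, the
#: only contract being that they sit on the lateral side of the tibia).
SCHEMAS: dict[SchemaId, LandmarkSchema] = {
    SchemaId.PRE_ORIGINAL: _schema(
        SchemaId.PRE_ORIGINAL,
        110,
        femoral_shaft_proximal_pair=(44, 0),
        femoral_shaft_distal_pair=(42, 2),
        femoral_notch_pair=(22, 23),
        tibial_shaft_proximal_pair=(84, 46),
        tibial_shaft_distal_pair=(85, 45),
        tibial_spine_groove=(65,),
        fibula_indices=tuple(range(100, 110)),
    ),
    SchemaId.PRE_EXTENDED: _schema(
        SchemaId.PRE_EXTENDED,
        134,
        femoral_shaft_proximal_pair=(121, 115),
        femoral_shaft_distal_pair=(42, 2),
        femoral_notch_pair=(22, 23),
        tibial_shaft_proximal_pair=(83, 47),
        tibial_shaft_distal_pair=(133, 127),
        tibial_spine_groove=(65,),
        fibula_indices=tuple(range(100, 110)),
    ),
    SchemaId.POST_ORIGINAL: _schema(
        SchemaId.POST_ORIGINAL,
        157,
        femoral_shaft_proximal_pair=(28, 0),
        femoral_shaft_distal_pair=(26, 2),
        femoral_notch_pair=(83, 84),
        tibial_shaft_proximal_pair=(48, 31),
        tibial_shaft_distal_pair=(50, 29),
        tibial_plateau_centre_pair=(117, 139),
        fibula_indices=tuple(range(147, 157)),
    ),
    SchemaId.POST_EXTENDED: _schema(
        SchemaId.POST_EXTENDED,
        181,
        femoral_shaft_proximal_pair=(168, 162),
        femoral_shaft_distal_pair=(26, 2),
        femoral_notch_pair=(83, 84),
        tibial_shaft_proximal_pair=(48, 31),
        tibial_shaft_distal_pair=(180, 174),
        tibial_plateau_centre_pair=(117, 139),
        fibula_indices=tuple(range(147, 157)),
    ),
}


def get_schema(schema_id: "SchemaId | str") -> LandmarkSchema:
    return SCHEMAS[_as_schema_id(schema_id)]


@dataclass
class LandmarkSet:
    """Ordered 2D landmarks for one knee radiograph under a named schema."""

    schema_id: SchemaId
    points: np.ndarray  # (n_points, 2) float64, columns (x, y) in pixels
    image_id: str = ""
    source: str = "manual"  # "manual" | "automatic"

    def __post_init__(self) -> None:
        self.schema_id = _as_schema_id(self.schema_id)
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError(f"points must be (n, 2), got {pts.shape}")
        self.points = pts

    @property
    def schema(self) -> LandmarkSchema:
        return SCHEMAS[self.schema_id]

    @property
    def n_points(self) -> int:
        return int(self.points.shape[0])

    def copy(self, **changes) -> "LandmarkSet":
        out = replace(self, **changes)
        if "points" not in changes:
            out.points = self.points.copy()
        return out


class PtsFormatError(ValueError):
    """Raised when a pts file cannot be parsed or fails its declared contract."""


_HEADER_RE = re.compile(r"^\s*(version|n_points)\s*:\s*(\S+)\s*$")


def read_pts(path: "str | Path", schema_id: "SchemaId | str | None" = None,
             image_id: str | None = None, source: str = "manual") -> LandmarkSet:
    """Read a pts landmark file.

    The dialect is the plain-text points format widely used for landmark
    annotations::

        version: 1
        n_points: 110
        {
        512.25 133.0
        ...
        }

    Parameters
    ----------
    path:
        File to read.
    schema_id:
        Expected schema.  If given, the declared point count must match the
        schema and the returned set is fully validated.  If None, a bare
        (unvalidated-against-schema) set is returned using the schema whose
        point count matches, which must be unique (it is: 110/134/157/181).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    header: dict[str, str] = {}
    i = 0
    while i < len(lines):
        m = _HEADER_RE.match(lines[i])
        if not m:
            break
        header[m.group(1)] = m.group(2)
        i += 1
    if "n_points" not in header:
        raise PtsFormatError(f"{path}: missing 'n_points' header")
    try:
        n_declared = int(header["n_points"])
    except ValueError:
        raise PtsFormatError(f"{path}: bad n_points {header['n_points']!r}") from None
    if i >= len(lines) or lines[i].strip() != "{":
        raise PtsFormatError(f"{path}: expected '{{' after header")
    i += 1
    coords: list[tuple[float, float]] = []
    closed = False
    for line in lines[i:]:
        s = line.strip()
        if not s:
            continue
        if s == "}":
            closed = True
            break
        parts = s.split()
        if len(parts) != 2:
            raise PtsFormatError(f"{path}: bad coordinate line {line!r}")
        try:
            coords.append((float(parts[0]), float(parts[1])))
        except ValueError:
            raise PtsFormatError(f"{path}: bad coordinate line {line!r}") from None
    if not closed:
        raise PtsFormatError(f"{path}: missing closing '}}'")
    if len(coords) != n_declared:
        raise PtsFormatError(
            f"{path}: header declares {n_declared} points but file has {len(coords)}"
        )
    pts = np.array(coords, dtype=float).reshape(n_declared, 2)
    if not np.all(np.isfinite(pts)):
        raise PtsFormatError(f"{path}: non-finite coordinate")

    if schema_id is None:
        matches = [s for s in SCHEMAS.values() if s.n_points == n_declared]
        if len(matches) != 1:
            raise PtsFormatError(
                f"{path}: cannot infer schema for point count {n_declared}"
            )
        sid = matches[0].schema_id
        return LandmarkSet(sid, pts, image_id=image_id or path.stem, source=source)

    sid = _as_schema_id(schema_id)
    schema = SCHEMAS[sid]
    if n_declared != schema.n_points:
        raise PtsFormatError(
            f"{path}: {n_declared} points, schema {sid} expects {schema.n_points}"
        )
    return validate(LandmarkSet(sid, pts, image_id=image_id or path.stem, source=source))


def write_pts(ls: LandmarkSet, path: "str | Path") -> None:
    """Write a LandmarkSet in the pts dialect (re-readable to 1e-6 px)."""
    path = Path(path)
    lines = ["version: 1", f"n_points: {ls.n_points}", "{"]
    lines += [f"{x:.6f} {y:.6f}" for x, y in ls.points]
    lines.append("}")
    path.write_text("\n".join(lines) + "\n")


def flip_horizontal(ls: LandmarkSet, image_width: float) -> LandmarkSet:
    """Mirror a landmark set about the vertical image midline.

    Each x becomes ``(image_width - 1) - x`` (integer pixel centres), y and
    point order are unchanged.  Used to normalise right knees to the
    left-knee convention; the signed aFTA is invariant to it because the
    lateral side is re-detected from the fibula.
    """
    if image_width <= 0:
        raise ValueError("image_width must be positive")
    if np.max(ls.points[:, 0]) >= image_width:
        raise ValueError("image_width must exceed the maximum x coordinate")
    pts = ls.points.copy()
    pts[:, 0] = (image_width - 1.0) - pts[:, 0]
    return ls.copy(points=pts)


def _axis_endpoint(points: np.ndarray, idx: tuple[int, ...]) -> np.ndarray:
    return points[list(idx)].mean(axis=0)


def _axis_role_pairs(schema: LandmarkSchema) -> list[tuple[str, str]]:
    """Pairs of roles that form bone axes for this schema (degeneracy checks)."""
    pairs = [
        ("femoral_shaft_proximal_pair", "femoral_shaft_distal_pair"),
        ("femoral_shaft_proximal_pair", "femoral_notch_pair"),
        ("tibial_shaft_proximal_pair", "tibial_shaft_distal_pair"),
    ]
    if schema.is_postop:
        pairs.append(("tibial_shaft_distal_pair", "tibial_plateau_centre_pair"))
    else:
        pairs.append(("tibial_shaft_distal_pair", "tibial_spine_groove"))
    return pairs


def validate(ls: LandmarkSet) -> LandmarkSet:
    """Check all LandmarkSet invariants; return the set unchanged if valid.

    Raises ``ValueError`` on a wrong point count, non-finite coordinates, or
    an axis whose two resolved endpoints coincide within 1e-6 px (the axis
    direction would be undefined).
    """
    schema = ls.schema
    if ls.n_points != schema.n_points:
        raise ValueError(
            f"{ls.image_id or 'landmark set'}: {ls.n_points} points, "
            f"schema {schema.schema_id} expects {schema.n_points}"
        )
    if not np.all(np.isfinite(ls.points)):
        raise ValueError(f"{ls.image_id or 'landmark set'}: non-finite coordinate")
    for role_a, role_b in _axis_role_pairs(schema):
        pa = _axis_endpoint(ls.points, schema.role(role_a))
        pb = _axis_endpoint(ls.points, schema.role(role_b))
        if np.linalg.norm(pa - pb) < COINCIDENT_TOL_PX:
            raise ValueError(
                f"{ls.image_id or 'landmark set'}: degenerate axis "
                f"({role_a} and {role_b} endpoints coincide)"
            )
    return ls
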