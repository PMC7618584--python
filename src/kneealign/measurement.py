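"""Anatomical femorotibial angle (aFTA) computation.

The aFTA is the signed angle between the femoral and tibial anatomical
(shaft) axes on an AP knee radiograph, with valgus ("knock-knee") positive
and varus ("bow-leg") negative.  In a healthy population the aFTA sits
around 5-7 degrees of valgus; values above 7 degrees indicate a valgus
deformity and values below 0 a varus deformity.  After knee replacement an
alignment between 2.4 and 7.2 degrees of valgus is commonly quoted as
acceptable.

Each axis is a straight line connecting two resolved endpoints, where an
endpoint is either a single landmark or the midpoint of a symmetric landmark
pair straddling the bone.  Eight named measurement recipes are provided
(two per landmark schema): a shafts-only variant and a variant that pulls
the distal femoral endpoint to the intercondylar notch and (for original
schemas) the proximal tibial endpoint to the tibial spine groove or the
tibial plateau centre.

Sign convention
---------------
Axis orientation ``theta`` is measured from the image-down direction and is
positive when the proximal-to-distal axis vector tilts toward the lateral
side of the knee.  The lateral side is auto-detected from the fibula
landmarks (the fibula is the lateral bone of the lower leg), which makes the
signed aFTA invariant to horizontal flips.  With both orientations
lateralized this way,

    aFTA = theta_tibia - theta_femur

which is positive exactly when the distal tibia deviates laterally relative
to the femoral axis, i.e. valgus.  Equivalently, on the raw (un-lateralized)
angles aFTA = lateral_sign * (theta_tib_raw - theta_fem_raw).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .landmarks import (
    COINCIDENT_TOL_PX,
    LandmarkSet,
    SchemaId,
    get_schema,
)

__all__ = [
    "AxisEndpoint",
    "MeasurementDefinition",
    "AngleResult",
    "builtin_definitions",
    "definitions_for_schema",
    "axis_orientation",
    "detect_lateral_sign",
    "compute_aFTA",
    "classify",
    "in_acceptable_postop_range",
    "measure_set",
    "ACCEPTABLE_POSTOP_RANGE_DEG",
    "USUAL_ALIGNMENT_RANGE_DEG",
    "VALGUS_DEFORMITY_THRESHOLD_DEG",
]

#: Acceptable post-operative alignment band (degrees of valgus), inclusive.
ACCEPTABLE_POSTOP_RANGE_DEG = (2.4, 7.2)
#: Usual (healthy) alignment band in degrees, inclusive.
USUAL_ALIGNMENT_RANGE_DEG = (5.0, 7.0)
#: Above this angle the alignment is classified as a valgus deformity.
VALGUS_DEFORMITY_THRESHOLD_DEG = 7.0


@dataclass(frozen=True)
class AxisEndpoint:
    """One resolved endpoint of a bone axis.

    ``indices`` holds one landmark index (the endpoint is that landmark) or
    two (the endpoint is the midpoint of the pair).
    """

    indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.indices) not in (1, 2):
            raise ValueError("AxisEndpoint takes one or two landmark indices")

    @property
    def kind(self) -> str:
        return "single_index" if len(self.indices) == 1 else "midpoint_of_pair"

    def resolve(self, points: np.ndarray) -> np.ndarray:
        """Endpoint coordinates (x, y) given the full landmark array."""
        return points[list(self.indices)].mean(axis=0)


def mid(i: int, j: int) -> AxisEndpoint:
    return AxisEndpoint((i, j))


def single(i: int) -> AxisEndpoint:
    return AxisEndpoint((i,))


@dataclass(frozen=True)
class MeasurementDefinition:
    """A named aFTA recipe: femoral and tibial axis endpoints by index."""

    name: str
    schema_id: SchemaId
    femoral_a: AxisEndpoint
    femoral_b: AxisEndpoint
    tibial_a: AxisEndpoint
    tibial_b: AxisEndpoint

    def __post_init__(self) -> None:
        n = get_schema(self.schema_id).n_points
        for ep in (self.femoral_a, self.femoral_b, self.tibial_a, self.tibial_b):
            if any(i < 0 or i >= n for i in ep.indices):
                raise ValueError(
                    f"{self.name}: endpoint index out of range for {self.schema_id}"
                )


def builtin_definitions() -> dict[str, MeasurementDefinition]:
    """The eight published aFTA measurement recipes, keyed by name.

    Two recipes per schema: "fem-tib-shafts" connects shaft centre points
    only; the "fem-notch"/"tib-spines" variants anchor the distal femoral
    axis at the intercondylar notch and, for the original schemas, the
    distal tibial axis at the spine groove (pre) or plateau centre (post).
    """
    P, PX = SchemaId.PRE_ORIGINAL, SchemaId.PRE_EXTENDED
    Q, QX = SchemaId.POST_ORIGINAL, SchemaId.POST_EXTENDED
    defs = [
        MeasurementDefinition(
            "Pre-fem-tib-shafts", P,
            mid(44, 0), mid(42, 2), mid(84, 46), mid(85, 45)),
        MeasurementDefinition(
            "Pre-fem-notch-tib-spines", P,
            mid(44, 0), mid(22, 23), mid(85, 45), single(65)),
        MeasurementDefinition(
            "PreX-fem-tib-shafts", PX,
            mid(121, 115), mid(42, 2), mid(83, 47), mid(133, 127)),
        MeasurementDefinition(
            "PreX-fem-notch-tib-shafts", PX,
            mid(121, 115), mid(22, 23), mid(83, 47), mid(133, 127)),
        MeasurementDefinition(
            "Post-fem-tib-shafts", Q,
            mid(28, 0), mid(26, 2), mid(48, 31), mid(50, 29)),
        MeasurementDefinition(
            "Post-fem-notch-tib-spines", Q,
            mid(28, 0), mid(83, 84), mid(50, 29), mid(117, 139)),
        MeasurementDefinition(
            "PostX-fem-tib-shafts", QX,
            mid(168, 162), mid(26, 2), mid(48, 31), mid(180, 174)),
        MeasurementDefinition(
            "PostX-fem-notch-tib-shafts", QX,
            mid(168, 162), mid(83, 84), mid(48, 31), mid(180, 174)),
    ]
    return {d.name: d for d in defs}


def definitions_for_schema(schema_id: "SchemaId | str") -> dict[str, MeasurementDefinition]:
    """The builtin definitions applicable to one schema (two per schema)."""
    sid = SchemaId(schema_id) if not isinstance(schema_id, SchemaId) else schema_id
    return {k: d for k, d in builtin_definitions().items() if d.schema_id == sid}


def axis_orientation(proximal: np.ndarray, distal: np.ndarray,
                     lateral_sign: int) -> float:
    """Orientation of a bone axis in degrees.

    Measured from the image-down direction (+y), positive when the
    proximal-to-distal vector tilts toward the lateral side
    (``lateral_sign`` +1 if lateral is toward +x, -1 otherwise).
    Result lies in (-90, 90) for any distally-descending axis.
    """
    proximal = np.asarray(proximal, dtype=float)
    distal = np.asarray(distal, dtype=float)
    v = distal - proximal
    if float(np.hypot(v[0], v[1])) < COINCIDENT_TOL_PX:
        raise ValueError("degenerate axis: endpoints coincide")
    theta = math.degrees(math.atan2(v[0], v[1])) * lateral_sign
    if not -90.0 < theta < 90.0:
        raise ValueError(
            f"axis orientation {theta:.2f} deg outside (-90, 90); "
            "axis does not run proximal-to-distal down the image"
        )
    return theta


def detect_lateral_sign(ls: LandmarkSet) -> int:
    """+1 if the lateral side of the knee is toward +x, else -1.

    Uses the anatomical fact that the fibula is lateral: compares the mean x
    of the fibula landmarks with the mean x of the tibial shaft axis
    endpoint landmarks.
    """
    schema = ls.schema
    fibula = schema.role("fibula_indices")
    tib = (schema.role("tibial_shaft_proximal_pair")
           + schema.role("tibial_shaft_distal_pair"))
    fib_x = float(ls.points[list(fibula), 0].mean())
    tib_x = float(ls.points[list(tib), 0].mean())
    return 1 if fib_x > tib_x else -1


@dataclass(frozen=True)
class AngleResult:
    """A signed aFTA measurement with axis orientations and classification.

    ``theta_fem_deg`` / ``theta_tib_deg`` are the lateralized axis
    orientations (see module docstring); ``aFTA_deg`` equals their
    difference (tibial minus femoral), positive for valgus.
    """

    aFTA_deg: float
    theta_fem_deg: float
    theta_tib_deg: float
    definition_name: str
    classification: str
    in_acceptable_range: bool
    lateral_sign: int


def classify(aFTA_deg: float) -> str:
    """Clinical alignment band for a signed aFTA.

    varus below 0; usual alignment in [5, 7]; valgus deformity above 7.
    The unnamed band [0, 5) is labelled ``neutral_low`` here purely for
    completeness, without claiming clinical meaning.
    """
    if not math.isfinite(aFTA_deg):
        raise ValueError("aFTA must be finite")
    if aFTA_deg < 0.0:
        return "varus"
    if aFTA_deg > VALGUS_DEFORMITY_THRESHOLD_DEG:
        return "valgus_deformity"
    if USUAL_ALIGNMENT_RANGE_DEG[0] <= aFTA_deg <= USUAL_ALIGNMENT_RANGE_DEG[1]:
        return "usual"
    return "neutral_low"


def in_acceptable_postop_range(aFTA_deg: float) -> bool:
    """True iff the angle lies in the acceptable post-operative band
    [2.4, 7.2] degrees of valgus (inclusive at both ends)."""
    if not math.isfinite(aFTA_deg):
        raise ValueError("aFTA must be finite")
    lo, hi = ACCEPTABLE_POSTOP_RANGE_DEG
    return lo <= aFTA_deg <= hi


def _oriented(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Order two endpoints proximal-first (smaller y, i.e. higher in image)."""
    return (a, b) if a[1] <= b[1] else (b, a)


def compute_aFTA(ls: LandmarkSet, d: MeasurementDefinition) -> AngleResult:
    """Measure the signed aFTA of one landmark set under one recipe."""
    if ls.schema_id != d.schema_id:
        raise ValueError(
            f"schema mismatch: landmarks are {ls.schema_id}, "
            f"definition {d.name} targets {d.schema_id}"
        )
    pts = ls.points
    lat = detect_lateral_sign(ls)
    fem_p, fem_d = _oriented(d.femoral_a.resolve(pts), d.femoral_b.resolve(pts))
    tib_p, tib_d = _oriented(d.tibial_a.resolve(pts), d.tibial_b.resolve(pts))
    theta_fem = axis_orientation(fem_p, fem_d, lat)
    theta_tib = axis_orientation(tib_p, tib_d, lat)
    afta = theta_tib - theta_fem
    return AngleResult(
        aFTA_deg=afta,
        theta_fem_deg=theta_fem,
        theta_tib_deg=theta_tib,
        definition_name=d.name,
        classification=classify(afta),
        in_acceptable_range=in_acceptable_postop_range(afta),
        lateral_sign=lat,
    )


def measure_set(ls: LandmarkSet,
                definitions: "Iterable[MeasurementDefinition] | None" = None,
                ) -> list[AngleResult]:
    """Apply every applicable (or the given) definition to one landmark set."""
    if definitions is None:
        definitions = definitions_for_schema(ls.schema_id).values()
    return [compute_aFTA(ls, d) for d in definitions]
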