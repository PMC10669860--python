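"""Eruption-quotient geometry on a simplified occlusal plane.

A panoramic radiograph is a distorted 2D projection with region-dependent
magnification, so absolute millimetre distances measured on it are not
comparable across images.  The method therefore measures two perpendicular
distances from a *simplified occlusal plane* — the line through the highest
mesial cusp point of the first molar and the highest distal cusp point of
the second molar — down to the mesial cementoenamel junctions (CEJ) of the
second and the third molar, and forms their dimensionless quotient

    Q = d(M2 CEJ) / d(M3 CEJ)        (default direction)

which is invariant to uniform projection magnification.  As the third molar
erupts its CEJ approaches the occlusal plane, d(M3) falls toward d(M2) and
Q rises toward about 1, so Q increases with age.

Coordinates follow the raster convention (x rightward, y downward), so the
apical direction of a mandibular tooth is increasing y; perpendicular
distances are signed positive on the apical side of the plane.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum

from .landmarks import MEASUREMENT_LABELS, RadiographRecord

__all__ = [
    "OcclusalLine",
    "QuotientMeasurement",
    "EligibilityConfig",
    "EligibilityResult",
    "ExclusionReason",
    "DegenerateGeometryError",
    "NonPositiveDistanceError",
    "build_occlusal_line",
    "perpendicular_distance",
    "round_half_up",
    "measure_quotient",
    "tooth_angulation",
    "assess_eligibility",
]

logger = logging.getLogger(__name__)

_COINCIDENT_TOL = 1e-9


class DegenerateGeometryError(ValueError):
    """Anchors coincide (occlusal line undefined) or an axis has zero length."""


class NonPositiveDistanceError(ValueError):
    """A CEJ point lies on or coronal to the occlusal line."""


class ExclusionReason(str, Enum):
    MESIAL_ANGULATION_GT_30 = "MESIAL_ANGULATION_GT_30"
    DISTAL_ANGULATION = "DISTAL_ANGULATION"
    MISSING_LANDMARK = "MISSING_LANDMARK"
    OCCLUSAL_PLANE_UNDEFINED = "OCCLUSAL_PLANE_UNDEFINED"
    NONPOSITIVE_DISTANCE = "NONPOSITIVE_DISTANCE"


@dataclass(frozen=True)
class OcclusalLine:
    """The simplified occlusal plane as an infinite line through two anchors."""

    p1: tuple[float, float]
    p2: tuple[float, float]

    @property
    def direction(self) -> tuple[float, float]:
        """Unit direction vector from p1 to p2."""
        dx = self.p2[0] - self.p1[0]
        dy = self.p2[1] - self.p1[1]
        norm = math.hypot(dx, dy)
        return (dx / norm, dy / norm)

    @property
    def length(self) -> float:
        return math.hypot(self.p2[0] - self.p1[0], self.p2[1] - self.p1[1])


def build_occlusal_line(m1_mesial_cusp: tuple[float, float],
                        m2_distal_cusp: tuple[float, float]) -> OcclusalLine:
    """Build the simplified occlusal plane from its two cusp anchors.

    The line is treated as infinite in both directions: the perpendicular
    foot of the third molar CEJ routinely falls distal to the anchor
    segment, which is intentional.
    """
    line = OcclusalLine(p1=tuple(map(float, m1_mesial_cusp)),
                        p2=tuple(map(float, m2_distal_cusp)))
    if line.length <= _COINCIDENT_TOL:
        raise DegenerateGeometryError(
            f"occlusal plane undefined: anchors {m1_mesial_cusp} and "
            f"{m2_distal_cusp} coincide"
        )
    return line


def perpendicular_distance(line: OcclusalLine, p: tuple[float, float]) -> float:
    """Signed perpendicular (orthogonal) distance from the line to point ``p``.

    Magnitude is |cross(p2-p1, p-p1)| / |p2-p1|.  The sign is positive when
    ``p`` lies on the apical side of the line — the side toward larger y for
    any non-vertical line under the raster convention — and negative on the
    occlusal side, independent of the order of the two anchors.
    """
    if line.length <= _COINCIDENT_TOL:
        raise DegenerateGeometryError("degenerate occlusal line")
    dx = line.p2[0] - line.p1[0]
    dy = line.p2[1] - line.p1[1]
    cross = dx * (p[1] - line.p1[1]) - dy * (p[0] - line.p1[0])
    s = cross / math.hypot(dx, dy)
    # s increases along (-dy, dx); that direction points apically (toward
    # +y) iff dx > 0.  Flip for dx < 0 so the sign does not depend on which
    # anchor came first; for an exactly vertical line fall back to dy.
    if dx < 0 or (dx == 0 and dy < 0):
        s = -s
    return s


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round with ties away from zero (clinical recording convention)."""
    factor = 10.0 ** decimals
    return math.floor(abs(value) * factor + 0.5) / factor * math.copysign(1.0, value)


@dataclass(frozen=True)
class QuotientMeasurement:
    """The two perpendicular CEJ distances and their eruption quotient.

    ``d_m2`` / ``d_m3`` are the reported lengths (millimetres when the
    record is calibrated and rounding is on, else the unrounded values in
    the same units as ``d_m2_raw``).  The raw fields keep the unrounded
    values; ``units`` records whether they are "mm" or "px".  ``length_a``
    and ``length_b`` alias the second- and third-molar lengths in the order
    the measurements are taken (M2 first).
    """

    d_m2: float
    d_m3: float
    quotient: float
    direction: str  # "m2_over_m3" | "m3_over_m2"
    rounded: bool
    units: str  # "mm" | "px"
    d_m2_raw: float = field(repr=False, default=math.nan)
    d_m3_raw: float = field(repr=False, default=math.nan)

    @property
    def length_a(self) -> float:
        return self.d_m2

    @property
    def length_b(self) -> float:
        return self.d_m3


def measure_quotient(record: RadiographRecord, direction: str = "m2_over_m3",
                     round_lengths: bool = True) -> QuotientMeasurement:
    """Measure the eruption quotient on one annotated radiograph record.

    Both CEJ points must lie strictly apical to the occlusal plane
    (positive signed distance); otherwise :class:`NonPositiveDistanceError`
    is raised and the record should be excluded rather than yield a
    sign-flipped quotient.

    When ``round_lengths`` is true and the record carries a millimetre
    calibration, each length is converted to mm and rounded half-up to one
    decimal place before the division, mirroring clinical recording of
    lengths to 0.1 mm; without calibration, rounding pixels would be
    scale-dependent, so it is skipped with a warning.
    """
    if direction not in ("m2_over_m3", "m3_over_m2"):
        raise ValueError(f"unknown quotient direction {direction!r}")
    missing = [lbl for lbl in MEASUREMENT_LABELS if lbl not in record.landmarks]
    if missing:
        raise ValueError(f"record {record.key} not measurable: missing {missing}")

    line = build_occlusal_line(record.point("M1_MESIAL_CUSP"),
                               record.point("M2_DISTAL_CUSP"))
    d_m2_px = perpendicular_distance(line, record.point("M2_MESIAL_CEJ"))
    d_m3_px = perpendicular_distance(line, record.point("M3_MESIAL_CEJ"))
    if d_m2_px <= 0 or d_m3_px <= 0:
        raise NonPositiveDistanceError(
            f"record {record.key}: CEJ on or coronal to the occlusal plane "
            f"(d_m2={d_m2_px:.3g}, d_m3={d_m3_px:.3g} px)"
        )

    if record.mm_per_px is not None:
        d_m2_raw = d_m2_px * record.mm_per_px
        d_m3_raw = d_m3_px * record.mm_per_px
        units = "mm"
    else:
        d_m2_raw, d_m3_raw = d_m2_px, d_m3_px
        units = "px"

    do_round = bool(round_lengths)
    if do_round and units != "mm":
        logger.warning(
            "record %s: length rounding requested but no mm calibration; skipped",
            record.key,
        )
        do_round = False
    if do_round:
        d_m2 = round_half_up(d_m2_raw, 1)
        d_m3 = round_half_up(d_m3_raw, 1)
        if d_m2 <= 0 or d_m3 <= 0:
            raise NonPositiveDistanceError(
                f"record {record.key}: length rounds to 0.0 mm"
            )
    else:
        d_m2, d_m3 = d_m2_raw, d_m3_raw

    q = d_m2 / d_m3 if direction == "m2_over_m3" else d_m3 / d_m2
    return QuotientMeasurement(
        d_m2=d_m2,
        d_m3=d_m3,
        quotient=q,
        direction=direction,
        rounded=do_round,
        units=units,
        d_m2_raw=d_m2_raw,
        d_m3_raw=d_m3_raw,
    )


def _mesial_sign(side: int, orientation: str) -> float:
    """x-direction of 'mesial' for the given third molar.

    In the standard panoramic orientation the patient's left (tooth 38) is
    on the viewer's right, so mesial (toward the midline) is decreasing x
    for 38 and increasing x for 48.  ``orientation='flipped'`` inverts both.
    """
    if orientation not in ("standard", "flipped"):
        raise ValueError(f"unknown image orientation {orientation!r}")
    sign = -1.0 if side == 38 else 1.0
    if orientation == "flipped":
        sign = -sign
    return sign


def tooth_angulation(m3_axis: tuple[tuple[float, float], tuple[float, float]],
                     m2_axis: tuple[tuple[float, float], tuple[float, float]],
                     side: int,
                     orientation: str = "standard") -> float:
    """Signed angulation of the third molar relative to the second molar axis.

    Each axis is given as (coronal point, apical point).  The magnitude is
    the acute angle between the two long axes in [0, 90] degrees; the sign
    is positive when the third molar's crown tilts mesially (Winter-style
    mesio-angulation) and negative for disto-angulation.
    """
    (c3, a3), (c2, a2) = m3_axis, m2_axis
    v3 = (c3[0] - a3[0], c3[1] - a3[1])  # apical -> coronal
    v2 = (c2[0] - a2[0], c2[1] - a2[1])
    n3 = math.hypot(*v3)
    n2 = math.hypot(*v2)
    if n3 <= _COINCIDENT_TOL or n2 <= _COINCIDENT_TOL:
        raise DegenerateGeometryError("zero-length tooth axis")
    u3 = (v3[0] / n3, v3[1] / n3)
    u2 = (v2[0] / n2, v2[1] / n2)
    cos_lines = abs(u3[0] * u2[0] + u3[1] * u2[1])
    angle = math.degrees(math.acos(min(1.0, cos_lines)))
    # component of the M3 crown direction perpendicular to the M2 axis
    dot = u3[0] * u2[0] + u3[1] * u2[1]
    perp_x = u3[0] - dot * u2[0]
    mesial_x = _mesial_sign(side, orientation)
    if angle == 0.0 or perp_x == 0.0:
        return angle  # parallel axes: no tilt direction
    return angle if perp_x * mesial_x > 0 else -angle


@dataclass(frozen=True)
class EligibilityConfig:
    """Study eligibility thresholds for third molar angulation.

    Mesial angulation strictly greater than ``mesial_angle_limit`` excludes;
    any distal angulation beyond ``distal_angle_limit`` (+ ``angle_tolerance``)
    excludes regardless of degree.
    """

    mesial_angle_limit: float = 30.0
    distal_angle_limit: float = 0.0
    angle_tolerance: float = 0.0
    orientation: str = "standard"

    def __post_init__(self) -> None:
        if self.mesial_angle_limit < 0 or self.distal_angle_limit < 0 or self.angle_tolerance < 0:
            raise ValueError("angle limits and tolerance must be >= 0")


@dataclass(frozen=True)
class EligibilityResult:
    included: bool
    reasons: tuple[ExclusionReason, ...]
    angulation_deg: float | None = None
    angulation_assessed: bool = False

    def __post_init__(self) -> None:
        assert self.included == (len(self.reasons) == 0)


def assess_eligibility(record: RadiographRecord,
                       config: EligibilityConfig | None = None) -> EligibilityResult:
    """Apply the study inclusion criteria to one record.

    All applicable exclusion reasons are accumulated (no short-circuit): a
    record can be both unmeasurable and disto-angulated.  Records lacking
    the axis landmarks cannot have their angulation assessed and are not
    excluded for it (the angle check is simply flagged as not assessed).
    The mesial boundary is strict: exactly at the limit is still included.
    """
    config = config or EligibilityConfig()
    reasons: list[ExclusionReason] = []

    missing = [lbl for lbl in MEASUREMENT_LABELS if lbl not in record.landmarks]
    line = None
    if "M1_MESIAL_CUSP" in record.landmarks and "M2_DISTAL_CUSP" in record.landmarks:
        try:
            line = build_occlusal_line(record.point("M1_MESIAL_CUSP"),
                                       record.point("M2_DISTAL_CUSP"))
        except DegenerateGeometryError:
            reasons.append(ExclusionReason.OCCLUSAL_PLANE_UNDEFINED)
    if missing:
        reasons.append(ExclusionReason.MISSING_LANDMARK)
    elif line is not None:
        d_m2 = perpendicular_distance(line, record.point("M2_MESIAL_CEJ"))
        d_m3 = perpendicular_distance(line, record.point("M3_MESIAL_CEJ"))
        if d_m2 <= 0 or d_m3 <= 0:
            reasons.append(ExclusionReason.NONPOSITIVE_DISTANCE)

    angle: float | None = None
    assessed = False
    if record.has_axes:
        try:
            angle = tooth_angulation(
                (record.point("M3_AXIS_CORONAL"), record.point("M3_AXIS_APICAL")),
                (record.point("M2_AXIS_CORONAL"), record.point("M2_AXIS_APICAL")),
                side=record.side,
                orientation=config.orientation,
            )
            assessed = True
        except DegenerateGeometryError:
            reasons.append(ExclusionReason.MISSING_LANDMARK)
    if assessed and angle is not None:
        if angle > config.mesial_angle_limit + config.angle_tolerance:
            reasons.append(ExclusionReason.MESIAL_ANGULATION_GT_30)
        if angle < -(config.distal_angle_limit + config.angle_tolerance):
            reasons.append(ExclusionReason.DISTAL_ANGULATION)

    return EligibilityResult(
        included=not reasons,
        reasons=tuple(reasons),
        angulation_deg=angle,
        angulation_assessed=assessed,
    )
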