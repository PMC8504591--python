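"""Slit-camera projection geometry, plane scaling and compliance checks.

Coordinate convention (one side at a time): the origin sits at the nearest
detector edge (first/last row or column of pixels), the axis points toward the
detector center, and distances are in millimetres.  A negative field-boundary
position ``x_fov`` means the X-ray field extends beyond the detector edge.

The boundary formula follows from similar triangles between the source, the
irradiated foil plane, the slit aperture and the detector:

    x_fov = [x_edge + (y_foil/y_slit) (x_slit - x_edge)
             - (y_foil/y_source) x_source] / (1 - y_foil/y_source)

where ``x_edge`` is the position where the fluorescence signal inside the
camera vanishes, ``x_slit`` the slit position, ``y_foil``/``y_slit`` the foil
and slit heights above the detector plane, and ``y_source``/``x_source`` the
source position (``y_source`` is the SID).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ConfigurationError, DegenerateGeometryError

SIDES = ("chest_wall", "left", "right", "nipple")


@dataclass(frozen=True)
class SlitGeometry:
    """Measured positions defining one camera setup on one detector side.

    All values in mm.  ``y_foil = 0`` (foil on the detector plane) is allowed
    as a degenerate reference case; otherwise 0 < y_slit < y_foil < y_source.
    """

    y_foil: float
    y_slit: float
    x_slit: float
    y_source: float
    x_source: float
    side: str = "chest_wall"

    def __post_init__(self) -> None:
        vals = (self.y_foil, self.y_slit, self.x_slit, self.y_source, self.x_source)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("geometry values must be finite")
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}")
        if not (0 < self.y_slit < self.y_source):
            raise ValueError("need 0 < y_slit < y_source")
        if self.y_foil < 0 or self.y_foil >= self.y_source:
            raise DegenerateGeometryError("need 0 <= y_foil < y_source")
        if self.y_foil != 0 and self.y_foil <= self.y_slit:
            raise ValueError("need y_slit < y_foil (or y_foil = 0)")


@dataclass(frozen=True)
class FieldMeasurement:
    """One measured field boundary: view label, x_edge and x_fov (mm).

    Negative ``x_fov`` means the field extends beyond the detector edge.
    ``difference_mm`` is relative to a reference view when assigned.
    """

    view: str
    x_edge: float
    x_fov: float
    side: str = "chest_wall"
    difference_mm: float | None = None


@dataclass(frozen=True)
class LightFieldMarker:
    """Light-field edge marker position (mm) and its height above the detector."""

    x_light: float
    marker_height: float = 0.0


@dataclass(frozen=True)
class ComplianceLimits:
    """Regulatory limits: fractions of SID and the EU absolute limit (mm)."""

    sid_fraction: float = 0.02
    eu_limit_mm: float = 5.0
    congruence_sid_fraction: float = 0.02

    def __post_init__(self) -> None:
        if min(self.sid_fraction, self.eu_limit_mm, self.congruence_sid_fraction) <= 0:
            raise ValueError("compliance limits must be positive")


def fov_boundary(geom: SlitGeometry, x_edge: float) -> float:
    """Field boundary position x_fov (mm) from the measured edge x_edge."""
    denom = 1.0 - geom.y_foil / geom.y_source
    if abs(denom) < 1e-12:
        raise DegenerateGeometryError("y_foil equals y_source")
    num = (
        x_edge
        + (geom.y_foil / geom.y_slit) * (geom.x_slit - x_edge)
        - (geom.y_foil / geom.y_source) * geom.x_source
    )
    return num / denom


def invert_fov_boundary(geom: SlitGeometry, x_fov: float) -> float:
    """Edge position x_edge (mm) that maps to the given field boundary."""
    slit_factor = 1.0 - geom.y_foil / geom.y_slit
    if abs(slit_factor) < 1e-12:
        raise DegenerateGeometryError("y_foil equals y_slit")
    denom = 1.0 - geom.y_foil / geom.y_source
    if abs(denom) < 1e-12:
        raise DegenerateGeometryError("y_foil equals y_source")
    return (
        x_fov * denom
        - (geom.y_foil / geom.y_slit) * geom.x_slit
        + (geom.y_foil / geom.y_source) * geom.x_source
    ) / slit_factor


def project_to_plane(distance_mm: float, height_mm: float, sid_mm: float) -> float:
    """Scale a distance measured at ``height_mm`` above the detector to the
    detector plane, using the central-projection magnification sid/(sid-h)."""
    if sid_mm <= 0:
        raise DegenerateGeometryError("SID must be positive")
    if not 0 <= height_mm < sid_mm:
        raise DegenerateGeometryError("need 0 <= height < SID")
    return distance_mm * sid_mm / (sid_mm - height_mm)


def field_beyond_from_support_reading(
    reading_mm: float,
    marker_offset_mm: float,
    height_mm: float,
    sid_mm: float,
    round_to: float = 0.1,
) -> float:
    """Convert an external-sensor reading taken on the breast support into the
    field extent beyond the detector edge, at the detector plane.

    The sensor reads the light-field-marker-to-field-edge distance on top of
    the support; it is projected down to the detector plane and the marker's
    distance to the detector edge (measured on the radiograph) is subtracted.
    The result is rounded to the reporting precision (0.1 mm by default).
    """
    projected = project_to_plane(reading_mm, height_mm, sid_mm)
    beyond = projected - marker_offset_mm
    if round_to:
        beyond = round(beyond / round_to) * round_to
    return beyond


@dataclass(frozen=True)
class SideVerdict:
    """Pass/fail of one detector side against one ruleset."""

    side: str
    view: str
    x_fov: float
    overhang_mm: float  # extent beyond the detector edge (0 if inside)
    limit_mm: float
    passed: bool
    rule: str
    note: str = ""


RULESETS = ("MQSA", "CFR", "EU")


def check_compliance(
    measurements: dict[str, FieldMeasurement],
    sid_mm: float,
    limits: ComplianceLimits | None = None,
    ruleset: str = "MQSA",
) -> list[SideVerdict]:
    """Check per-side field measurements against a regulatory ruleset.

    * CFR: on every provided side, the field must not extend beyond the
      detector edge by more than ``sid_fraction`` x SID.
    * MQSA: the CFR rule, plus the chest-wall side must actually extend
      beyond the detector edge (x_fov < 0); a chest-wall measurement is
      therefore required.
    * EU: the extension beyond the detector must not exceed ``eu_limit_mm``.
    """
    if sid_mm <= 0:
        raise ConfigurationError("SID must be positive")
    rs = ruleset.upper()
    if rs not in RULESETS:
        raise ConfigurationError(f"unknown ruleset {ruleset!r}; use one of {RULESETS}")
    if limits is None:
        limits = ComplianceLimits()
    if rs == "MQSA" and "chest_wall" not in measurements:
        raise ConfigurationError("MQSA ruleset requires a chest_wall measurement")

    verdicts = []
    for side, m in measurements.items():
        overhang = max(0.0, -m.x_fov)
        if rs == "EU":
            limit = limits.eu_limit_mm
            ok = overhang <= limit
            note = ""
        else:
            limit = limits.sid_fraction * sid_mm
            ok = overhang <= limit
            note = ""
            if rs == "MQSA" and side == "chest_wall" and m.x_fov >= 0:
                ok = False
                note = "beam does not reach past the chest-wall edge"
        verdicts.append(
            SideVerdict(side, m.view, m.x_fov, overhang, limit, ok, rs, note)
        )
    return verdicts


def light_xray_misalignment(
    x_fov: float, marker: LightFieldMarker, sid_mm: float
) -> float:
    """Absolute light/X-ray field misalignment on one side, mm.

    A marker read at a height above the detector is first projected to the
    detector plane.
    """
    x_light = marker.x_light
    if marker.marker_height > 0:
        x_light = project_to_plane(x_light, marker.marker_height, sid_mm)
    return abs(x_fov - x_light)


def congruence_check(
    misalignments_mm: dict[str, float],
    sid_mm: float,
    limits: ComplianceLimits | None = None,
) -> tuple[float, float, bool]:
    """Sum per-side misalignments and compare with the congruence limit.

    Returns ``(summed misalignment, limit, passed)``.
    """
    if limits is None:
        limits = ComplianceLimits()
    total = sum(abs(v) for v in misalignments_mm.values())
    limit = limits.congruence_sid_fraction * sid_mm
    return total, limit, total <= limit
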