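"""Closed-form geometry of the linac collision-free cylinder.

A C-arm linear accelerator sweeps its treatment head on a circle about the
isocenter.  Sweeping that circle along the gantry rotation axis gives a
cylinder of radius ``r`` (isocenter to collimator front cover) and length
``L`` (superior-inferior extent of the head): everything inside the cylinder
is clear of the head at every gantry angle, everything outside it collides
for some arc of gantry angles.

This module provides the coordinate conventions, the couch-rotation frame
transform, the ellipse obtained by cutting the cylinder with a CT slice
plane at a nonzero couch angle, the clearance half-angle of a violating
point, and circular angle-interval arithmetic.

Conventions
-----------
* Patient frame (head-first supine): ``lateral`` = patient left (+),
  ``vertical`` = anterior (+), ``longitudinal`` = superior (+); origin at
  the plan isocenter.
* Room frame: shares the vertical axis; the gantry rotation axis is the
  room longitudinal axis.  A couch rotation by ``theta`` about the vertical
  axis maps patient coordinates to room coordinates via
  ``[[cos t, sin t], [-sin t, cos t]]`` acting on (lateral, longitudinal).
* Gantry/polar angle of a room point: ``atan2(lateral, vertical)`` in
  degrees mapped to (-180, 180]; 0 deg is vertical-up (IEC 61217 gantry
  zero, beam from above), -90 deg displays as IEC 270 deg.
* All interface angles are degrees; radians appear only inside formulas.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "LinacClearError",
    "InvalidGeometryError",
    "UnsupportedCouchAngleError",
    "InvalidMarginError",
    "NoViolationError",
    "MachineGeometry",
    "Point3",
    "EllipseParams",
    "AngleInterval",
    "wrap_deg",
    "circular_diff_deg",
    "polar_angle_deg",
    "to_room_frame",
    "cross_section",
    "effective_radius",
    "clearance_phi",
    "interval_overlap",
    "merge_intervals",
]


class LinacClearError(Exception):
    """Base class for all package errors."""


class InvalidGeometryError(LinacClearError, ValueError):
    """Geometric inputs are non-finite, non-positive or otherwise unusable."""


class UnsupportedCouchAngleError(InvalidGeometryError):
    """Couch angles with |theta| >= 90 deg have no slice-plane ellipse."""


class InvalidMarginError(InvalidGeometryError):
    """Safety margin must satisfy 0 <= margin < clearance radius."""


class NoViolationError(LinacClearError, ValueError):
    """The clearance half-angle is only defined for points outside the cylinder."""


# --------------------------------------------------------------------------
# angle helpers


def wrap_deg(angle):
    """Wrap angle(s) in degrees to the interval (-180, 180]."""
    a = np.asarray(angle, dtype=float)
    w = (a + 180.0) % 360.0 - 180.0
    w = np.where(w <= -180.0, w + 360.0, w)
    if np.ndim(angle) == 0:
        return float(w)
    return w


def circular_diff_deg(a, b):
    """Absolute circular difference |a - b| in degrees, in [0, 180]."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0
    d = np.where(d > 180.0, 360.0 - d, d)
    if np.ndim(a) == 0 and np.ndim(b) == 0:
        return float(d)
    return d


def polar_angle_deg(lateral_mm, vertical_mm):
    """Gantry-style polar angle of a room-frame point.

    0 deg is vertical-up; positive toward patient left; range (-180, 180].
    """
    ang = np.degrees(np.arctan2(lateral_mm, vertical_mm))
    return wrap_deg(ang)


# --------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class MachineGeometry:
    """Clearance-cylinder parameters of a C-arm linac.

    Parameters
    ----------
    clearance_radius_mm : float
        Distance from the isocenter to the collimator front cover (the
        radius ``r`` of the collision-free cylinder).
    head_length_mm : float
        Superior-inferior extent ``L`` of the treatment head; sets the
        longitudinal window within which collisions are possible.
    gantry_zero : str
        Angle convention tag.  Fixed to IEC 61217 (0 deg = beam from above,
        increasing toward patient left for head-first supine).
    """

    clearance_radius_mm: float
    head_length_mm: float
    gantry_zero: str = "IEC 61217"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.clearance_radius_mm) and self.clearance_radius_mm > 0):
            raise InvalidGeometryError("clearance_radius_mm must be finite and > 0")
        if not (math.isfinite(self.head_length_mm) and self.head_length_mm > 0):
            raise InvalidGeometryError("head_length_mm must be finite and > 0")

    @classmethod
    def from_config(cls, path: str | Path) -> "MachineGeometry":
        """Load machine geometry from a YAML or JSON config file.

        The file must provide ``clearance_radius_mm`` and ``head_length_mm``;
        there are no defaults because these are machine-specific measured
        quantities.
        """
        text = Path(path).read_text()
        data = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
        if not isinstance(data, dict):
            raise InvalidGeometryError(f"machine config {path} is not a mapping")
        try:
            return cls(
                clearance_radius_mm=float(data["clearance_radius_mm"]),
                head_length_mm=float(data["head_length_mm"]),
            )
        except KeyError as exc:
            raise InvalidGeometryError(f"machine config missing required key {exc}") from exc

    def to_config(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(
                {
                    "clearance_radius_mm": self.clearance_radius_mm,
                    "head_length_mm": self.head_length_mm,
                }
            )
        )


PATIENT = "patient"
ROOM = "room"


@dataclass(frozen=True)
class Point3:
    """A point in millimetres relative to the plan isocenter, with a frame tag."""

    lateral_mm: float
    vertical_mm: float
    longitudinal_mm: float
    frame: str = PATIENT

    def __post_init__(self) -> None:
        for v in (self.lateral_mm, self.vertical_mm, self.longitudinal_mm):
            if not math.isfinite(v):
                raise InvalidGeometryError("Point3 coordinates must be finite")
        if self.frame not in (PATIENT, ROOM):
            raise InvalidGeometryError(f"unknown frame tag {self.frame!r}")

    @property
    def norm(self) -> float:
        return math.sqrt(
            self.lateral_mm**2 + self.vertical_mm**2 + self.longitudinal_mm**2
        )


@dataclass(frozen=True)
class EllipseParams:
    """Cross-section of the clearance cylinder in a transverse CT slice.

    ``a_mm``/``b_mm`` are the semi-axes along the lateral/vertical patient
    axes, ``d_mm`` the signed lateral offset of the ellipse center from the
    isocenter, ``z_mm`` the slice longitudinal position.  At couch angle 0
    the section is a circle (``a = b``, ``d = 0``).
    """

    a_mm: float
    b_mm: float
    d_mm: float
    z_mm: float

    def __post_init__(self) -> None:
        if not (self.a_mm >= self.b_mm > 0):
            raise InvalidGeometryError("ellipse requires a_mm >= b_mm > 0")


@dataclass(frozen=True)
class AngleInterval:
    """A directed arc on the circle, from ``start_deg`` increasing to ``end_deg``.

    Angles are interpreted modulo 360 and may wrap through +-180.  The width
    is ``(end - start) mod 360`` except that a raw span of exactly 360
    degrees denotes the full circle (see :meth:`full`).
    """

    start_deg: float
    end_deg: float

    def __post_init__(self) -> None:
        for v in (self.start_deg, self.end_deg):
            if not math.isfinite(v):
                raise InvalidGeometryError("interval endpoints must be finite")

    @classmethod
    def full(cls) -> "AngleInterval":
        return cls(-180.0, 180.0)

    @property
    def width_deg(self) -> float:
        span = self.end_deg - self.start_deg
        if abs(span) >= 360.0:
            return 360.0
        return span % 360.0

    @property
    def is_full(self) -> bool:
        return self.width_deg >= 360.0

    def contains(self, angle_deg: float, tol: float = 1e-9) -> bool:
        """Membership of an angle (mod 360), endpoints inclusive."""
        if self.is_full:
            return True
        rel = (angle_deg - self.start_deg) % 360.0
        return rel <= self.width_deg + tol or rel >= 360.0 - tol

    def normalized(self) -> "AngleInterval":
        """Endpoints wrapped to (-180, 180], preserving the swept arc."""
        if self.is_full:
            return AngleInterval.full()
        s = wrap_deg(self.start_deg)
        return AngleInterval(s, wrap_deg(s + self.width_deg))


# --------------------------------------------------------------------------
# operations


def to_room_frame(p: Point3, couch_angle_deg: float) -> Point3:
    """Rotate a patient-frame point into the room frame for a couch angle.

    The rotation is about the vertical axis through the isocenter; positive
    couch angle swings the patient's superior end toward the patient's left.
    The vertical component is unchanged and the norm is preserved;
    ``to_room_frame(p, 0)`` is the identity.
    """
    if p.frame != PATIENT:
        raise InvalidGeometryError("to_room_frame expects a patient-frame point")
    if not math.isfinite(couch_angle_deg):
        raise InvalidGeometryError("couch angle must be finite")
    t = math.radians(couch_angle_deg)
    c, s = math.cos(t), math.sin(t)
    x, z = p.lateral_mm, p.longitudinal_mm
    return Point3(
        lateral_mm=c * x + s * z,
        vertical_mm=p.vertical_mm,
        longitudinal_mm=-s * x + c * z,
        frame=ROOM,
    )


def rotate_to_room(lateral_mm, vertical_mm, longitudinal_mm, couch_angle_deg: float):
    """Vectorised couch rotation; returns room-frame (lateral, vertical, longitudinal)."""
    t = math.radians(couch_angle_deg)
    c, s = math.cos(t), math.sin(t)
    x = np.asarray(lateral_mm, dtype=float)
    z = np.asarray(longitudinal_mm, dtype=float)
    return c * x + s * z, np.asarray(vertical_mm, dtype=float), -s * x + c * z


def cross_section(
    r_eff_mm: float,
    couch_angle_deg: float,
    z_slice_mm: float,
    z_iso_mm: float,
    abs_offset: bool = False,
) -> EllipseParams:
    """Ellipse cut by the transverse slice plane through the clearance cylinder.

    With couch angle ``theta`` the cylinder axis makes an angle ``theta``
    with the slice normal, so the section is an ellipse with semi-axes
    ``a = r_eff / cos(theta)`` (lateral) and ``b = r_eff`` (vertical), its
    center offset laterally by ``d = -(z_slice - z_iso) * tan(theta)``.  The
    sign of ``d`` follows from the couch rotation convention used by
    :func:`to_room_frame`; ``abs_offset=True`` drops the sign and places all
    off-center sections on the positive-lateral side (magnitude-only form).
    """
    if not (math.isfinite(r_eff_mm) and r_eff_mm > 0):
        raise InvalidGeometryError("effective radius must be finite and > 0")
    if not math.isfinite(couch_angle_deg) or abs(couch_angle_deg) >= 90.0:
        raise UnsupportedCouchAngleError(
            f"couch angle {couch_angle_deg} deg unsupported (|theta| must be < 90)"
        )
    t = math.radians(couch_angle_deg)
    a = r_eff_mm / math.cos(t)
    d = -(z_slice_mm - z_iso_mm) * math.tan(t)
    if abs_offset:
        d = abs(d)
    return EllipseParams(a_mm=a, b_mm=r_eff_mm, d_mm=d, z_mm=z_slice_mm)


def effective_radius(r_mm: float, margin_mm: float) -> float:
    """Clearance radius after applying a safety margin (``r - margin``).

    The margin absorbs setup error and modelling uncertainty by shrinking
    the radius used for detection; it must satisfy ``0 <= margin < r``.
    """
    if not (math.isfinite(r_mm) and r_mm > 0):
        raise InvalidGeometryError("clearance radius must be finite and > 0")
    if not math.isfinite(margin_mm) or margin_mm < 0 or margin_mm >= r_mm:
        raise InvalidMarginError(
            f"margin {margin_mm} mm invalid; need 0 <= margin < r = {r_mm} mm"
        )
    return r_mm - margin_mm


def clearance_phi(rho_mm: float, r_eff_mm: float) -> float:
    """Collision half-angle of a violating point, ``arccos(r_eff / rho)`` in degrees.

    A point at radial distance ``rho`` from the gantry axis is struck by the
    head for gantry angles within ``phi`` of the point's polar angle.  Only
    defined for ``rho >= r_eff`` (points outside or on the cylinder).
    """
    if not (math.isfinite(r_eff_mm) and r_eff_mm > 0):
        raise InvalidGeometryError("effective radius must be finite and > 0")
    if not math.isfinite(rho_mm) or rho_mm < r_eff_mm:
        raise NoViolationError(
            f"rho = {rho_mm} mm is inside the clearance radius {r_eff_mm} mm"
        )
    return math.degrees(math.acos(r_eff_mm / rho_mm))


def interval_overlap(a: AngleInterval, b: AngleInterval) -> bool:
    """True iff the two circular arcs share at least one angle (wrap-aware)."""
    return a.contains(b.start_deg) or b.contains(a.start_deg)


def merge_intervals(intervals: Iterable[AngleInterval]) -> list[AngleInterval]:
    """Union of circular arcs as a list of disjoint normalized arcs.

    The result is sorted by start angle in (-180, 180]; a covering union
    collapses to the single full-circle interval.
    """
    ivs = [iv for iv in intervals]
    if not ivs:
        return []
    if any(iv.is_full for iv in ivs):
        return [AngleInterval.full()]
    # unroll onto [0, 720) so wrapping arcs become plain segments
    segs = []
    for iv in ivs:
        s = iv.start_deg % 360.0
        segs.append((s, s + iv.width_deg))
    segs.sort()
    merged: list[list[float]] = []
    for s, e in segs:
        if merged and s <= merged[-1][1] + 1e-12:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    # wrap-around: the trailing segment may reach past 360 into the leading
    # one; merging can cascade into subsequent segments, so iterate
    while len(merged) > 1 and merged[-1][1] >= merged[0][0] + 360.0 - 1e-12:
        merged[0][0] = merged[-1][0] - 360.0
        merged[0][1] = max(merged[0][1], merged[-1][1] - 360.0)
        merged.pop()
        while len(merged) > 1 and merged[1][0] <= merged[0][1] + 1e-12:
            merged[0][1] = max(merged[0][1], merged[1][1])
            merged.pop(1)
    if merged and merged[0][1] - merged[0][0] >= 360.0 - 1e-12:
        return [AngleInterval.full()]
    out = [AngleInterval(s, e).normalized() for s, e in merged]
    out.sort(key=lambda iv: iv.start_deg)
    return out
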