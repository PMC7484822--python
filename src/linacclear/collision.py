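"""Collision detection against the clearance cylinder.

Every contour vertex of the body and couch structures (with edges
subdivided so discretization cannot hide a protruding corner) is rotated
into the room frame at the field's couch angle.  A point inside the
longitudinal head window whose radial distance ``rho`` from the gantry
axis exceeds the effective clearance radius violates the safe space; it is
struck by the treatment head for gantry angles within
``phi = arccos(r_eff / rho)`` of its polar angle.

Two interval rules are provided:

* ``max_point`` — violating points are clustered into regions and each
  region contributes the arc centered on its deepest point (the classical
  single-point rule).  It can under-cover regions containing widely
  separated moderate-depth points.
* ``union`` (default) — every violating point contributes its own arc and
  the arcs are merged; exact with respect to the cylinder model.

A field is red when its collision arcs overlap the planned gantry arc;
the plan-level verdict is red when any field is red.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .geometry import (
    AngleInterval,
    InvalidGeometryError,
    LinacClearError,
    MachineGeometry,
    Point3,
    PATIENT,
    ROOM,
    circular_diff_deg,
    clearance_phi,
    effective_radius,
    interval_overlap,
    merge_intervals,
    polar_angle_deg,
    rotate_to_room,
    wrap_deg,
)
from .structures import PlanSpec, StructureSet

__all__ = [
    "ViolationPoint",
    "ViolationRegion",
    "FieldResult",
    "CollisionReport",
    "densify_polygon",
    "find_violations",
    "group_regions",
    "region_interval",
    "union_intervals",
    "oracle_collision_set",
    "oracle_intervals",
    "check_plan",
    "collision_map",
    "write_collision_map_csv",
]


@dataclass(frozen=True)
class ViolationPoint:
    """A contour point outside the effective clearance cylinder."""

    patient_point: Point3
    room_point: Point3
    rho_mm: float
    polar_deg: float
    structure_name: str


@dataclass
class ViolationRegion:
    """A cluster of violating points; ``max_point`` is the deepest member."""

    points: list[ViolationPoint]

    def __post_init__(self) -> None:
        if not self.points:
            raise InvalidGeometryError("a violation region cannot be empty")

    @property
    def max_point(self) -> ViolationPoint:
        return max(self.points, key=lambda p: p.rho_mm)


@dataclass
class FieldResult:
    field_name: str
    couch_angle_deg: float
    planned_arc: AngleInterval
    collision_intervals: list[AngleInterval]
    violating_structures: list[str]
    overlap: bool

    @property
    def state(self) -> str:
        return "red" if self.overlap else "green"


@dataclass
class CollisionReport:
    """Per-field collision arcs and verdicts plus the plan-level flag."""

    fields: list[FieldResult]
    margin_mm: float
    method: str

    @property
    def calculated_collision(self) -> bool:
        return any(f.overlap for f in self.fields)

    def to_dict(self) -> dict:
        return {
            "margin_mm": round(self.margin_mm, 6),
            "method": self.method,
            "calculated_collision": self.calculated_collision,
            "fields": [
                {
                    "name": f.field_name,
                    "couch_angle_deg": round(f.couch_angle_deg, 6),
                    "planned_arc_deg": [
                        round(f.planned_arc.start_deg, 6),
                        round(f.planned_arc.end_deg, 6),
                    ],
                    "collision_intervals_deg": [
                        [round(iv.start_deg, 6), round(iv.end_deg, 6)]
                        for iv in f.collision_intervals
                    ],
                    "violating_structures": sorted(set(f.violating_structures)),
                    "overlap": f.overlap,
                    "state": f.state,
                }
                for f in self.fields
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2) + "\n"


def densify_polygon(vertices: np.ndarray, max_edge_mm: float = 5.0) -> np.ndarray:
    """Subdivide polygon edges to at most ``max_edge_mm`` segments.

    Testing contour vertices alone is sufficient for convex clearance
    regions only when edges are short; subdivision bounds the sagitta error
    of straight edges against the curved cylinder boundary.
    """
    v = np.asarray(vertices, dtype=float)
    closed = np.vstack([v, v[:1]])
    pieces = []
    for p, q in zip(closed[:-1], closed[1:]):
        n = max(1, int(math.ceil(float(np.hypot(*(q - p))) / max_edge_mm)))
        frac = np.arange(n, dtype=float)[:, None] / n
        pieces.append(p + frac * (q - p))
    return np.vstack(pieces)


def find_violations(
    structures: Sequence[StructureSet],
    machine: MachineGeometry,
    couch_angle_deg: float,
    isocenter: Point3,
    margin_mm: float,
    max_edge_mm: float = 5.0,
    window_offset_mm: float = 0.0,
) -> list[ViolationPoint]:
    """All contour points that leave the effective clearance cylinder.

    Structures (absolute patient coordinates) are re-referenced to the
    isocenter, rotated to the room frame at the couch angle, filtered to
    the longitudinal head window ``|u - offset| <= L/2`` and kept where
    ``rho > r_eff`` strictly — a point exactly on the boundary is safe
    (its collision arc is empty).
    """
    r_eff = effective_radius(machine.clearance_radius_mm, margin_mm)
    half_window = 0.5 * machine.head_length_mm
    out: list[ViolationPoint] = []
    for s in structures:
        for sl in s.slices:
            z_rel = sl.z_mm - isocenter.longitudinal_mm
            for poly in sl.polygons:
                pts = densify_polygon(poly, max_edge_mm)
                lat = pts[:, 0] - isocenter.lateral_mm
                vert = pts[:, 1] - isocenter.vertical_mm
                x_r, v_r, u_r = rotate_to_room(lat, vert, z_rel, couch_angle_deg)
                rho = np.hypot(x_r, v_r)
                keep = (np.abs(u_r - window_offset_mm) <= half_window) & (rho > r_eff)
                for i in np.nonzero(keep)[0]:
                    out.append(
                        ViolationPoint(
                            patient_point=Point3(float(lat[i]), float(vert[i]), float(z_rel)),
                            room_point=Point3(
                                float(x_r[i]), float(v_r[i]), float(u_r[i]), frame=ROOM
                            ),
                            rho_mm=float(rho[i]),
                            polar_deg=polar_angle_deg(float(x_r[i]), float(v_r[i])),
                            structure_name=s.name,
                        )
                    )
    return out


def group_regions(
    points: Sequence[ViolationPoint],
    polar_gap_deg: float = 5.0,
    z_gap_mm: float = 10.0,
) -> list[ViolationRegion]:
    """Single-linkage clustering of violating points into contiguous regions.

    Two points join when they are within ``polar_gap_deg`` (circular) AND
    ``z_gap_mm`` of each other; input is sorted by (structure, z, polar)
    first so the result is deterministic.
    """
    pts = sorted(points, key=lambda p: (p.structure_name, p.room_point.longitudinal_mm, p.polar_deg))
    n = len(pts)
    if n == 0:
        return []
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    polars = np.array([p.polar_deg for p in pts])
    zs = np.array([p.room_point.longitudinal_mm for p in pts])
    for i in range(n):
        close = (circular_diff_deg(polars, polars[i]) <= polar_gap_deg) & (
            np.abs(zs - zs[i]) <= z_gap_mm
        )
        for j in np.nonzero(close)[0]:
            ri, rj = find(i), find(int(j))
            if ri != rj:
                parent[max(ri, rj)] = min(ri, rj)
    groups: dict[int, list[ViolationPoint]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(pts[i])
    return [ViolationRegion(points=groups[k]) for k in sorted(groups)]


def region_interval(region: ViolationRegion, r_eff_mm: float) -> AngleInterval:
    """Collision arc from the region's deepest point (the max-point rule)."""
    mp = region.max_point
    phi = clearance_phi(mp.rho_mm, r_eff_mm)
    return AngleInterval(mp.polar_deg - phi, mp.polar_deg + phi).normalized()


def union_intervals(
    points: Sequence[ViolationPoint], r_eff_mm: float
) -> list[AngleInterval]:
    """Union of every point's individual collision arc, merged and normalized.

    Exact under the cylinder model: a gantry angle collides iff some point
    lies within its own clearance half-angle of it.
    """
    arcs = []
    for p in points:
        phi = clearance_phi(p.rho_mm, r_eff_mm)
        arcs.append(AngleInterval(p.polar_deg - phi, p.polar_deg + phi))
    return merge_intervals(arcs)


def oracle_collision_set(
    points: Sequence[ViolationPoint], r_eff_mm: float, step_deg: float = 0.1
) -> np.ndarray:
    """Brute-force colliding gantry angles on a regular grid.

    A grid angle ``g`` collides iff some point satisfies
    ``rho * cos(|polar - g|_circ) > r_eff`` — the projection of the point
    onto the head direction pokes past the clearance radius.  This is the
    enumeration equivalent of the closed-form arcs and serves as the
    independent reference in tests.
    """
    if step_deg <= 0:
        raise InvalidGeometryError("grid step must be > 0")
    grid = np.arange(-180.0, 180.0, step_deg)
    if not points:
        return grid[:0]
    polars = np.array([p.polar_deg for p in points])
    rhos = np.array([p.rho_mm for p in points])
    diff = np.radians(circular_diff_deg(grid[:, None], polars[None, :]))
    collides = (rhos[None, :] * np.cos(diff) > r_eff_mm).any(axis=1)
    return grid[collides]


def oracle_intervals(
    points: Sequence[ViolationPoint], r_eff_mm: float, step_deg: float = 0.1
) -> list[AngleInterval]:
    """Contiguous runs of the oracle grid, as angle intervals (wrap-aware)."""
    grid = np.arange(-180.0, 180.0, step_deg)
    colliding = oracle_collision_set(points, r_eff_mm, step_deg)
    if len(colliding) == 0:
        return []
    mask = np.isin(np.round(grid / step_deg).astype(int), np.round(colliding / step_deg).astype(int))
    if mask.all():
        return [AngleInterval.full()]
    # rotate so the scan starts at a clear angle, then collect runs
    start = int(np.argmin(mask))
    rolled = np.roll(mask, -start)
    arcs = []
    i = 0
    n = len(rolled)
    while i < n:
        if rolled[i]:
            j = i
            while j + 1 < n and rolled[j + 1]:
                j += 1
            a = grid[(start + i) % n]
            b = grid[(start + j) % n]
            arcs.append(AngleInterval(float(a), float(b)).normalized())
            i = j + 1
        else:
            i += 1
    arcs.sort(key=lambda iv: iv.start_deg)
    return arcs


def check_plan(
    plan: PlanSpec,
    structures: Sequence[StructureSet],
    machine: MachineGeometry,
    margin_mm: float,
    method: str = "union",
    max_edge_mm: float = 5.0,
    roiss: Sequence | None = None,
) -> CollisionReport:
    """Full per-field collision check of a plan.

    For each field, violating points at its couch angle are converted to
    collision arcs (by the selected rule) and intersected with the planned
    gantry arc; the field is red on overlap and the plan-level
    ``calculated_collision`` flag is the disjunction over fields.  Both
    body and couch structures rotate with the couch.  If matching
    safe-space ROIs are passed in ``roiss`` their states are set.
    """
    if method not in ("union", "max_point"):
        raise LinacClearError(f"unknown interval method {method!r}")
    for s in structures:
        if s.frame != PATIENT:
            raise LinacClearError(f"structure {s.name!r} is not in the patient frame")
    r_eff = effective_radius(machine.clearance_radius_mm, margin_mm)
    results = []
    for f in sorted(plan.fields, key=lambda f: f.order_index):
        points = find_violations(
            structures, machine, f.couch_angle_deg, plan.isocenter, margin_mm, max_edge_mm
        )
        if method == "union":
            intervals = union_intervals(points, r_eff)
        else:
            intervals = [region_interval(r, r_eff) for r in group_regions(points)]
            intervals = merge_intervals(intervals)
        hit = [iv for iv in intervals if interval_overlap(iv, f.arc)]
        violating = sorted(
            {
                p.structure_name
                for p in points
                if any(iv.contains(p.polar_deg) for iv in hit)
            }
        ) if hit else []
        results.append(
            FieldResult(
                field_name=f.name,
                couch_angle_deg=f.couch_angle_deg,
                planned_arc=f.arc,
                collision_intervals=intervals,
                violating_structures=violating,
                overlap=bool(hit),
            )
        )
    report = CollisionReport(fields=results, margin_mm=margin_mm, method=method)
    if roiss is not None:
        _mark_roiss(report, list(roiss))
    return report


def _mark_roiss(report: CollisionReport, roiss: list) -> None:
    by_name = {f.field_name: f for f in report.fields}
    if len(roiss) == 1:
        # single shared-couch-angle ROISS: red if any field collides
        roiss[0].set_state("red" if report.calculated_collision else "green")
        return
    for r in roiss:
        fr = by_name.get(r.field_name)
        if fr is not None:
            r.set_state(fr.state)


def collision_map(
    structures: Sequence[StructureSet],
    isocenter: Point3,
    machine: MachineGeometry,
    couch_angles: Sequence[float],
    margin_mm: float,
    gantry_step_deg: float = 1.0,
    max_edge_mm: float = 5.0,
) -> dict[float, list[AngleInterval]]:
    """Collision arcs (union rule) for each couch angle — the gantry-vs-couch chart.

    Angles follow the signed display convention: gantry -90 deg corresponds
    to IEC 270 deg.
    """
    r_eff = effective_radius(machine.clearance_radius_mm, margin_mm)
    out: dict[float, list[AngleInterval]] = {}
    for theta in couch_angles:
        if abs(theta) >= 90.0:
            raise InvalidGeometryError(f"couch angle {theta} out of range")
        pts = find_violations(structures, machine, theta, isocenter, margin_mm, max_edge_mm)
        out[float(theta)] = union_intervals(pts, r_eff)
    return out


def write_collision_map_csv(
    cmap: dict[float, list[AngleInterval]],
    path: str | Path,
    gantry_step_deg: float = 1.0,
) -> None:
    """Export a couch x gantry 0/1 grid (1 = collision) for chart plotting."""
    grid = np.arange(-180.0, 180.0, gantry_step_deg)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["couch_angle_deg"] + [f"{g:g}" for g in grid])
        for theta in sorted(cmap):
            ivs = cmap[theta]
            row = [1 if any(iv.contains(g) for iv in ivs) else 0 for g in grid]
            w.writerow([f"{theta:g}"] + row)
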