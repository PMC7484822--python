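"""Safe-space ROI (ROISS) construction.

The collision-free cylinder is rendered onto the patient CT as one closed
contour per covered slice — a circle of radius ``r_eff`` at couch angle 0,
an off-center ellipse otherwise — so a planner can see the clearance
boundary fused with the anatomy in any planning system that displays ROIs.
A plan with a single couch angle gets one ROISS; a plan mixing couch angles
gets one ROISS per field, named and ordered like the fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .geometry import (
    InvalidGeometryError,
    LinacClearError,
    MachineGeometry,
    cross_section,
    effective_radius,
)
from .structures import PlanSpec, StructureSet, StructureSlice, write_rtstruct, CTGrid
from .geometry import Point3

__all__ = ["SafeSpaceROI", "build_roiss", "roiss_for_plan", "write_roiss_rtstruct"]

GREEN = (0, 255, 0)
RED = (255, 0, 0)


@dataclass
class SafeSpaceROI:
    """Per-slice safe-space contours for one beam field.

    ``slices`` holds ``(z_mm, vertices)`` pairs with vertices an Nx2 array
    of (lateral, vertical) mm relative to the isocenter axis position;
    ``state`` is a traffic-light verdict set exactly once after collision
    checking (unset -> green/red).
    """

    field_name: str
    couch_angle_deg: float
    margin_mm: float
    slices: list[tuple[float, np.ndarray]]
    state: str = "unset"

    def set_state(self, state: str) -> None:
        if state not in ("green", "red"):
            raise ValueError(f"state must be green or red, got {state!r}")
        if self.state not in ("unset", state):
            raise ValueError(f"state already set to {self.state!r}")
        self.state = state

    @property
    def color(self) -> tuple[int, int, int]:
        return {"green": GREEN, "red": RED}.get(self.state, (255, 255, 0))

    def to_structure_set(
        self, isocenter_lateral_mm: float = 0.0, isocenter_vertical_mm: float = 0.0
    ) -> StructureSet:
        """Convert to a plain structure set (optionally re-centered on an isocenter)."""
        slices = [
            StructureSlice(
                z_mm=z,
                polygons=[np.asarray(v) + [isocenter_lateral_mm, isocenter_vertical_mm]],
            )
            for z, v in self.slices
        ]
        return StructureSet(name=self.field_name, slices=slices)


def build_roiss(
    machine: MachineGeometry,
    couch_angle_deg: float,
    isocenter_z_mm: float,
    slice_zs: Sequence[float],
    margin_mm: float,
    n_vertices: int = 180,
    window_offset_mm: float = 0.0,
    abs_offset: bool = False,
    field_name: str = "ROISS",
) -> SafeSpaceROI:
    """Build the safe-space ROI over a CT slice grid.

    For each slice within the longitudinal coverage window the elliptical
    cylinder section (margin applied via the effective radius) is sampled
    as an ``n_vertices``-gon, uniform in parametric angle; slices outside
    the window get no polygon.  The window covers slices whose room-frame
    longitudinal coordinate ``u = (z - z_iso) / cos(theta)`` satisfies
    ``|u - window_offset| <= L / 2``.
    """
    if n_vertices < 8:
        raise InvalidGeometryError("need at least 8 polygon vertices")
    zs = list(slice_zs)
    if any(b <= a for a, b in zip(zs, zs[1:])):
        raise InvalidGeometryError("slice_zs must be sorted strictly increasing")
    r_eff = effective_radius(machine.clearance_radius_mm, margin_mm)
    t = np.radians(couch_angle_deg)
    cos_t = np.cos(t)
    half_window = 0.5 * machine.head_length_mm

    param = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    unit = np.column_stack([np.cos(param), np.sin(param)])

    slices: list[tuple[float, np.ndarray]] = []
    for z in zs:
        u = (z - isocenter_z_mm) / cos_t
        if abs(u - window_offset_mm) > half_window:
            continue
        ell = cross_section(r_eff, couch_angle_deg, z, isocenter_z_mm, abs_offset=abs_offset)
        verts = unit * [ell.a_mm, ell.b_mm]
        verts[:, 0] += ell.d_mm
        slices.append((float(z), verts))
    return SafeSpaceROI(
        field_name=field_name,
        couch_angle_deg=couch_angle_deg,
        margin_mm=margin_mm,
        slices=slices,
    )


def roiss_for_plan(
    plan: PlanSpec,
    machine: MachineGeometry,
    slice_zs: Sequence[float],
    margin_mm: float,
    n_vertices: int = 180,
    abs_offset: bool = False,
) -> list[SafeSpaceROI]:
    """One ROISS per distinct couch-angle situation.

    If every field shares one couch angle a single ROISS is built; plans
    with multiple couch angles get one ROISS per field, named and ordered
    like the fields so the planner can match them unambiguously.
    """
    angles = {f.couch_angle_deg for f in plan.fields}
    fields = sorted(plan.fields, key=lambda f: f.order_index)
    if len(angles) == 1:
        return [
            build_roiss(
                machine,
                fields[0].couch_angle_deg,
                plan.isocenter.longitudinal_mm,
                slice_zs,
                margin_mm,
                n_vertices=n_vertices,
                abs_offset=abs_offset,
                field_name="ROISS",
            )
        ]
    return [
        build_roiss(
            machine,
            f.couch_angle_deg,
            plan.isocenter.longitudinal_mm,
            slice_zs,
            margin_mm,
            n_vertices=n_vertices,
            abs_offset=abs_offset,
            field_name=f.name,
        )
        for f in fields
    ]


def write_roiss_rtstruct(
    roiss_list: Sequence[SafeSpaceROI],
    path: str | Path,
    isocenter: Point3 | None = None,
    ref_geometry: CTGrid | None = None,
    overwrite: bool = False,
) -> None:
    """Export ROISS contours as RTSTRUCT, colored by their green/red state."""
    iso_lat = isocenter.lateral_mm if isocenter is not None else 0.0
    iso_vert = isocenter.vertical_mm if isocenter is not None else 0.0
    structures = [r.to_structure_set(iso_lat, iso_vert) for r in roiss_list]
    colors = {r.field_name: r.color for r in roiss_list}
    write_rtstruct(
        structures,
        path,
        ref_geometry=ref_geometry,
        colors=colors,
        overwrite=overwrite,
    )
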