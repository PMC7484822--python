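"""Deterministic synthetic phantoms and study scenarios.

Analytic stand-ins for patient anatomy — an elliptical torso, twin-circle
legs, a torso with arm lobes — plus parametric couches, a CT-like density
rasterizer and a scenario suite covering the qualitative collision
situations a clearance checker must get right: a safe coplanar pelvic
setup, a gantry-couch collision caused by a thick prone plate with a high
isocenter, a gantry-patient collision from an abducted leg, a gantry-couch
collision from a laterally shifted isocenter, and a noncoplanar
(couch-rotated) abdominal setup where the far couch end swings toward the
gantry.  Shapes are analytic so every expected violation has closed-form
ground truth; verdicts are constructed with at least 20 mm of radial slack
so small jitter or margin changes cannot flip them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .geometry import AngleInterval, InvalidGeometryError, MachineGeometry, Point3
from .structures import (
    BeamField,
    CTGrid,
    EmptyStructureError,
    PlanSpec,
    StructureSet,
    StructureSlice,
    build_couch_structure,
)

__all__ = [
    "PhantomSpec",
    "make_phantom",
    "make_ct_grid",
    "Scenario",
    "scenario_suite",
    "default_machine",
    "validation_cases",
]


def default_machine() -> MachineGeometry:
    """Machine geometry used by the scenario suite.

    400 mm isocenter-to-collimator clearance and a 600 mm head extent are
    typical C-arm values; real deployments must measure and supply their
    own (there are no package-level defaults for analysis entry points).
    """
    return MachineGeometry(clearance_radius_mm=400.0, head_length_mm=600.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric anatomy phantom.

    ``kind`` selects the shape family: ``torso`` (single ellipse),
    ``legs`` (two circles of radius ``vertical_semi_axis_mm`` separated by
    ``leg_separation_mm``), ``arms_up_torso`` (ellipse plus two arm
    lobes).  ``seed`` fixes the optional vertex jitter (<= 1 mm) so a
    spec always produces identical geometry.
    """

    kind: str = "torso"
    lateral_semi_axis_mm: float = 170.0
    vertical_semi_axis_mm: float = 110.0
    length_mm: float = 700.0
    center_lateral_mm: float = 0.0
    center_vertical_mm: float = 0.0
    center_z_mm: float = 0.0
    leg_separation_mm: float = 220.0
    arm_radius_mm: float = 45.0
    jitter_mm: float = 0.0
    seed: int = 0
    n_vertices: int = 120

    def __post_init__(self) -> None:
        if self.kind not in ("torso", "legs", "arms_up_torso"):
            raise InvalidGeometryError(f"unknown phantom kind {self.kind!r}")
        if min(self.lateral_semi_axis_mm, self.vertical_semi_axis_mm, self.length_mm) <= 0:
            raise InvalidGeometryError("phantom dimensions must be > 0")
        if self.jitter_mm < 0 or self.jitter_mm > 1.0:
            raise InvalidGeometryError("vertex jitter is limited to 1 mm")


def _ellipse(cx: float, cy: float, a: float, b: float, n: int) -> np.ndarray:
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.column_stack([cx + a * np.cos(t), cy + b * np.sin(t)])


def make_phantom(spec: PhantomSpec, slice_zs: Sequence[float]) -> StructureSet:
    """Rasterize a phantom spec onto the given slice grid as a BODY structure."""
    rng = np.random.default_rng(spec.seed)
    z_lo = spec.center_z_mm - 0.5 * spec.length_mm
    z_hi = spec.center_z_mm + 0.5 * spec.length_mm
    slices = []
    for z in slice_zs:
        if not (z_lo <= z <= z_hi):
            continue
        polys: list[np.ndarray] = []
        if spec.kind in ("torso", "arms_up_torso"):
            polys.append(
                _ellipse(
                    spec.center_lateral_mm,
                    spec.center_vertical_mm,
                    spec.lateral_semi_axis_mm,
                    spec.vertical_semi_axis_mm,
                    spec.n_vertices,
                )
            )
            if spec.kind == "arms_up_torso":
                for sign in (-1.0, 1.0):
                    polys.append(
                        _ellipse(
                            spec.center_lateral_mm
                            + sign * (spec.lateral_semi_axis_mm + spec.arm_radius_mm),
                            spec.center_vertical_mm + 0.5 * spec.vertical_semi_axis_mm,
                            spec.arm_radius_mm,
                            spec.arm_radius_mm,
                            max(24, spec.n_vertices // 3),
                        )
                    )
        else:  # legs: two disjoint circles
            r = spec.vertical_semi_axis_mm
            for sign in (-1.0, 1.0):
                polys.append(
                    _ellipse(
                        spec.center_lateral_mm + sign * 0.5 * spec.leg_separation_mm,
                        spec.center_vertical_mm,
                        r,
                        r,
                        max(24, spec.n_vertices // 2),
                    )
                )
        if spec.jitter_mm > 0:
            polys = [
                p + rng.uniform(-spec.jitter_mm, spec.jitter_mm, size=p.shape)
                for p in polys
            ]
        slices.append(StructureSlice(z_mm=float(z), polygons=polys))
    if not slices:
        raise EmptyStructureError("phantom lies entirely outside the slice range")
    return StructureSet(name="BODY", slices=slices)


def make_ct_grid(
    spec: PhantomSpec,
    slice_thickness_mm: float = 3.0,
    pixel_mm: float = 2.0,
    density_gcc: float = 1.0,
    pad_mm: float = 40.0,
) -> CTGrid:
    """Rasterize a phantom as a CT-like density grid (body density in air).

    Slices are 3 mm thick by default, matching a typical planning-CT
    protocol; pixels are filled with ``density_gcc`` inside the analytic
    shape and 0 outside.
    """
    a, b = spec.lateral_semi_axis_mm, spec.vertical_semi_axis_mm
    half_lat = a + abs(spec.center_lateral_mm) + spec.leg_separation_mm + pad_mm
    half_vert = b + abs(spec.center_vertical_mm) + pad_mm
    lat = np.arange(-half_lat, half_lat + pixel_mm, pixel_mm)
    vert = np.arange(-half_vert, half_vert + pixel_mm, pixel_mm)
    zs = np.arange(
        spec.center_z_mm - 0.5 * spec.length_mm,
        spec.center_z_mm + 0.5 * spec.length_mm + slice_thickness_mm,
        slice_thickness_mm,
    )
    L, V = np.meshgrid(lat, vert)
    if spec.kind == "legs":
        r = spec.vertical_semi_axis_mm
        mask2d = np.zeros(L.shape, dtype=bool)
        for sign in (-1.0, 1.0):
            cx = spec.center_lateral_mm + sign * 0.5 * spec.leg_separation_mm
            mask2d |= (L - cx) ** 2 + (V - spec.center_vertical_mm) ** 2 <= r**2
    else:
        mask2d = ((L - spec.center_lateral_mm) / a) ** 2 + (
            (V - spec.center_vertical_mm) / b
        ) ** 2 <= 1.0
        if spec.kind == "arms_up_torso":
            for sign in (-1.0, 1.0):
                cx = spec.center_lateral_mm + sign * (a + spec.arm_radius_mm)
                cy = spec.center_vertical_mm + 0.5 * b
                mask2d |= (L - cx) ** 2 + (V - cy) ** 2 <= spec.arm_radius_mm**2
    density = np.repeat(mask2d[None, :, :].astype(float) * density_gcc, len(zs), axis=0)
    return CTGrid(
        density=density,
        spacing_mm=(slice_thickness_mm, pixel_mm, pixel_mm),
        origin_mm=(float(zs[0]), float(vert[0]), float(lat[0])),
    )


# --------------------------------------------------------------------------
# scenario suite


@dataclass
class Scenario:
    label: str
    plan: PlanSpec
    structures: list[StructureSet]
    expected_verdict: str  # "safe" | "collision"
    expected_structures: frozenset[str] = frozenset()
    machine: MachineGeometry = field(default_factory=default_machine)

    @property
    def slice_zs(self) -> list[float]:
        zs: set[float] = set()
        for s in self.structures:
            zs.update(s.slice_zs)
        return sorted(zs)


def _full_arc_plan(isocenter: Point3, couch_angle_deg: float = 0.0) -> PlanSpec:
    return PlanSpec(
        isocenter=isocenter,
        fields=(
            BeamField(
                name="arc1",
                couch_angle_deg=couch_angle_deg,
                arc=AngleInterval.full(),
                order_index=0,
            ),
        ),
    )


def scenario_suite(slice_spacing_mm: float = 10.0) -> list[Scenario]:
    """Five qualitative collision scenarios with geometry-forced verdicts.

    All verdicts carry >= 20 mm of radial slack relative to the 400 mm
    clearance radius, so they are stable under safety margins up to 10 mm
    and vertex jitter below 1 mm.  All couch angles are 0 except the
    noncoplanar scenario (30 deg).
    """
    zs = np.arange(-350.0, 350.0 + slice_spacing_mm, slice_spacing_mm)
    z_range = (-350.0, 350.0)
    scenarios = []

    # (a) safe pelvic setup: centered torso on a low flat couch.
    # Deepest point is a couch corner at rho = hypot(250, 170) ~ 302 mm.
    torso = make_phantom(
        PhantomSpec(kind="torso", center_vertical_mm=-40.0, length_mm=700.0), zs
    )
    couch = build_couch_structure(
        "flat", top_height_mm=-150.0, width_mm=500.0, thickness_mm=60.0,
        z_range_mm=z_range, slice_spacing_mm=slice_spacing_mm,
    )
    scenarios.append(
        Scenario(
            label="safe_pelvic",
            plan=_full_arc_plan(Point3(0.0, -40.0, 0.0)),
            structures=[torso, couch],
            expected_verdict="safe",
        )
    )

    # (b) prone plate, high isocenter: couch corner at hypot(250, 380) ~ 455 mm.
    torso_b = make_phantom(
        PhantomSpec(kind="torso", center_vertical_mm=-40.0, length_mm=700.0), zs
    )
    couch_b = build_couch_structure(
        "prone_plate", top_height_mm=-250.0, width_mm=500.0, thickness_mm=60.0,
        plate_thickness_mm=100.0, z_range_mm=z_range, slice_spacing_mm=slice_spacing_mm,
    )
    scenarios.append(
        Scenario(
            label="prone_plate_high_iso",
            plan=_full_arc_plan(Point3(0.0, 70.0, 0.0)),
            structures=[torso_b, couch_b],
            expected_verdict="collision",
            expected_structures=frozenset({"COUCH"}),
        )
    )

    # (c) leg treatment, healthy leg abducted: body point at rho ~ 540 mm.
    legs = make_phantom(
        PhantomSpec(
            kind="legs",
            vertical_semi_axis_mm=90.0,
            center_lateral_mm=125.0,
            center_vertical_mm=-60.0,
            leg_separation_mm=450.0,
            length_mm=700.0,
        ),
        zs,
    )
    couch_c = build_couch_structure(
        "flat", top_height_mm=-150.0, width_mm=440.0, thickness_mm=60.0,
        z_range_mm=z_range, slice_spacing_mm=slice_spacing_mm,
    )
    scenarios.append(
        Scenario(
            label="leg_abducted",
            plan=_full_arc_plan(Point3(-100.0, -60.0, 0.0)),
            structures=[legs, couch_c],
            expected_verdict="collision",
            expected_structures=frozenset({"BODY"}),
        )
    )

    # (d) abdominal plan, isocenter shifted toward the patient's right:
    # far couch corner at hypot(405, 170) ~ 439 mm.
    torso_d = make_phantom(
        PhantomSpec(kind="torso", center_vertical_mm=-40.0, length_mm=700.0), zs
    )
    couch_d = build_couch_structure(
        "flat", top_height_mm=-150.0, width_mm=530.0, thickness_mm=60.0,
        z_range_mm=z_range, slice_spacing_mm=slice_spacing_mm,
    )
    scenarios.append(
        Scenario(
            label="lateral_iso_offset",
            plan=_full_arc_plan(Point3(-140.0, -40.0, 0.0)),
            structures=[torso_d, couch_d],
            expected_verdict="collision",
            expected_structures=frozenset({"COUCH"}),
        )
    )

    # (e) noncoplanar abdominal plan (couch 30 deg): the superior couch end
    # swings toward the gantry; corner (250, -170, 350) maps to
    # rho = hypot(250 cos30 + 350 sin30, 170) ~ 427 mm inside the head window.
    torso_e = make_phantom(
        PhantomSpec(kind="torso", center_vertical_mm=-40.0, length_mm=700.0), zs
    )
    couch_e = build_couch_structure(
        "flat", top_height_mm=-150.0, width_mm=500.0, thickness_mm=60.0,
        z_range_mm=z_range, slice_spacing_mm=slice_spacing_mm,
    )
    scenarios.append(
        Scenario(
            label="noncoplanar_abdomen",
            plan=_full_arc_plan(Point3(0.0, -40.0, 0.0), couch_angle_deg=30.0),
            structures=[torso_e, couch_e],
            expected_verdict="collision",
            expected_structures=frozenset({"COUCH"}),
        )
    )
    return scenarios


# --------------------------------------------------------------------------
# desk-scale validation cases for margin sweeps


def validation_cases(
    n_cases: int,
    seed: int,
    slice_spacing_mm: float = 20.0,
) -> list[tuple[PlanSpec, list[StructureSet], list[StructureSet]]]:
    """Randomized coplanar setups with paired "true" (perturbed) geometry.

    Each case is a torso resting on a flat couch whose height, width and
    lateral offset relative to the isocenter vary so the deepest point
    sweeps through the clearance boundary.  The returned triple is
    ``(plan, planning_structures, true_structures)`` where the true
    geometry is the planning geometry under a rigid setup-error shift
    (normal, sigma 5 mm per axis, clipped to +-15 mm) — the desk-scale
    stand-in for the physically measured treatment-day position.
    """
    rng = np.random.default_rng(seed)
    z_range = (-300.0, 300.0)
    zs = np.arange(z_range[0], z_range[1] + slice_spacing_mm, slice_spacing_mm)
    cases = []
    for _ in range(n_cases):
        half_width = rng.uniform(230.0, 300.0)
        couch_top = rng.uniform(-330.0, -140.0)
        couch_lat = rng.uniform(-90.0, 90.0)
        b = rng.uniform(90.0, 120.0)
        a = rng.uniform(140.0, 180.0)
        torso = make_phantom(
            PhantomSpec(
                kind="torso",
                lateral_semi_axis_mm=a,
                vertical_semi_axis_mm=b,
                center_lateral_mm=couch_lat,
                center_vertical_mm=couch_top + b,
                length_mm=600.0,
            ),
            zs,
        )
        couch = build_couch_structure(
            "flat",
            top_height_mm=couch_top,
            width_mm=2.0 * half_width,
            thickness_mm=60.0,
            z_range_mm=z_range,
            slice_spacing_mm=slice_spacing_mm,
            lateral_center_mm=couch_lat,
        )
        plan = _full_arc_plan(Point3(0.0, 0.0, 0.0))
        shift = np.clip(rng.normal(0.0, 5.0, size=3), -15.0, 15.0)
        true_structures = [
            s.translated(float(shift[0]), float(shift[1]), float(shift[2]))
            for s in (torso, couch)
        ]
        cases.append((plan, [torso, couch], true_structures))
    return cases
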