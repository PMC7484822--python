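"""Plan and contour-structure I/O.

Structures are named stacks of closed planar polygons on transverse CT
slices, the representation shared by CT-derived body contours, parametric
couch models and the exported safe-space ROIs.  In memory, coordinates are
patient-frame millimetres (lateral, vertical) per slice at longitudinal
position ``z``; polygons are implicitly closed (the first vertex is not
repeated).  On disk, DICOM RTSTRUCT is the portable interchange format and
stores explicitly closed planar contours in the DICOM patient coordinate
system; a plain YAML/JSON plan spec carries the isocenter and per-field
couch angle and gantry arc.

DICOM patient axes for a head-first supine patient map to the package's
patient frame as ``x = lateral``, ``y = -vertical`` (DICOM y is posterior),
``z = longitudinal``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pydicom
import yaml
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid
from skimage import measure

from .geometry import (
    AngleInterval,
    InvalidGeometryError,
    LinacClearError,
    PATIENT,
    Point3,
)

__all__ = [
    "FormatError",
    "EmptyBodyError",
    "EmptyStructureError",
    "StructureSlice",
    "StructureSet",
    "BeamField",
    "PlanSpec",
    "CTGrid",
    "polygon_area_mm2",
    "read_rtstruct",
    "write_rtstruct",
    "read_rtplan",
    "load_plan",
    "save_plan",
    "body_from_ct",
    "build_couch_structure",
]

RTSTRUCT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.3"


class FormatError(LinacClearError, ValueError):
    """A file is not the expected DICOM/YAML/JSON structure."""


class EmptyBodyError(LinacClearError, ValueError):
    """No voxel reaches the body density threshold."""


class EmptyStructureError(LinacClearError, ValueError):
    """A structure with no slices cannot be built or written."""


def polygon_area_mm2(vertices: np.ndarray) -> float:
    """Shoelace area (mm^2) of an implicitly closed polygon, Nx2."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


@dataclass
class StructureSlice:
    """Closed 2-D polygons at one longitudinal position."""

    z_mm: float
    polygons: list[np.ndarray]  # each Nx2, columns (lateral_mm, vertical_mm)


@dataclass
class StructureSet:
    """A named per-slice contour stack in the patient frame.

    Slice ``z`` values are strictly increasing; every polygon has at least
    three vertices and nonzero area; closure is implicit in memory.
    """

    name: str
    slices: list[StructureSlice]
    frame: str = PATIENT

    def __post_init__(self) -> None:
        zs = [s.z_mm for s in self.slices]
        if any(b <= a for a, b in zip(zs, zs[1:])):
            raise InvalidGeometryError(f"{self.name}: slice z values must strictly increase")
        for s in self.slices:
            for poly in s.polygons:
                p = np.asarray(poly, dtype=float)
                if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] < 3:
                    raise InvalidGeometryError(
                        f"{self.name}: polygons need >= 3 (lateral, vertical) vertices"
                    )
                if polygon_area_mm2(p) <= 0:
                    raise InvalidGeometryError(f"{self.name}: degenerate zero-area polygon")

    def translated(self, d_lateral: float, d_vertical: float, d_longitudinal: float) -> "StructureSet":
        """Rigidly shifted copy (used for isocenter referencing and setup error)."""
        out = []
        for s in self.slices:
            out.append(
                StructureSlice(
                    z_mm=s.z_mm + d_longitudinal,
                    polygons=[
                        np.asarray(p, dtype=float) + [d_lateral, d_vertical]
                        for p in s.polygons
                    ],
                )
            )
        return StructureSet(name=self.name, slices=out, frame=self.frame)

    def mirrored_lateral(self) -> "StructureSet":
        """Copy mirrored about the lateral = 0 plane (vertex order reversed to keep orientation)."""
        out = []
        for s in self.slices:
            polys = []
            for p in s.polygons:
                q = np.asarray(p, dtype=float).copy()
                q[:, 0] *= -1.0
                polys.append(q[::-1])
            out.append(StructureSlice(z_mm=s.z_mm, polygons=polys))
        return StructureSet(name=self.name, slices=out, frame=self.frame)

    @property
    def slice_zs(self) -> list[float]:
        return [s.z_mm for s in self.slices]


@dataclass(frozen=True)
class BeamField:
    """One treatment field: couch angle plus the planned gantry arc."""

    name: str
    couch_angle_deg: float
    arc: AngleInterval
    order_index: int = 0

    def __post_init__(self) -> None:
        if abs(self.couch_angle_deg) >= 90.0:
            raise InvalidGeometryError(
                f"field {self.name}: |couch angle| must be < 90 deg"
            )


@dataclass(frozen=True)
class PlanSpec:
    """Isocenter (absolute patient coordinates of the structure set) and fields."""

    isocenter: Point3
    fields: tuple[BeamField, ...]

    def __post_init__(self) -> None:
        if len(self.fields) < 1:
            raise InvalidGeometryError("a plan needs at least one field")
        names = [f.name for f in self.fields]
        if len(set(names)) != len(names):
            raise InvalidGeometryError("field names must be unique")


@dataclass
class CTGrid:
    """A CT-like density grid (g/cm^3) on a regular 3-D lattice.

    ``density`` is indexed ``[z, vertical, lateral]``; ``spacing_mm`` and
    ``origin_mm`` are (z, vertical, lateral) with the origin at the center
    of voxel [0, 0, 0].
    """

    density: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=float)
        if self.density.ndim != 3:
            raise InvalidGeometryError("CT density grid must be 3-D")
        if any(s <= 0 for s in self.spacing_mm):
            raise InvalidGeometryError("CT voxel spacing must be > 0 on all axes")
        if np.any(self.density < 0):
            raise InvalidGeometryError("densities must be >= 0")

    @property
    def slice_zs(self) -> np.ndarray:
        nz = self.density.shape[0]
        return self.origin_mm[0] + self.spacing_mm[0] * np.arange(nz)

    def save_npz(self, path: str | Path) -> None:
        np.savez(
            path,
            density=self.density,
            spacing_mm=np.asarray(self.spacing_mm),
            origin_mm=np.asarray(self.origin_mm),
        )

    @classmethod
    def load_npz(cls, path: str | Path) -> "CTGrid":
        with np.load(path) as data:
            return cls(
                density=data["density"],
                spacing_mm=tuple(float(v) for v in data["spacing_mm"]),
                origin_mm=tuple(float(v) for v in data["origin_mm"]),
            )


# --------------------------------------------------------------------------
# RTSTRUCT


def _patient_to_dicom(lateral: np.ndarray, vertical: np.ndarray, z: float) -> np.ndarray:
    n = len(lateral)
    out = np.empty((n, 3), dtype=float)
    out[:, 0] = lateral
    out[:, 1] = -np.asarray(vertical, dtype=float)
    out[:, 2] = z
    return out


def read_rtstruct(path: str | Path, isocenter: Point3 | None = None) -> list[StructureSet]:
    """Read a DICOM RTSTRUCT into one :class:`StructureSet` per ROI.

    If ``isocenter`` (absolute patient-frame coordinates) is given, contours
    are re-referenced so that the isocenter becomes the origin; otherwise
    the absolute coordinates are kept.
    """
    try:
        ds = pydicom.dcmread(str(path))
    except Exception as exc:  # pydicom raises several unrelated types
        raise FormatError(f"{path}: not a readable DICOM file ({exc})") from exc
    if getattr(ds, "Modality", None) != "RTSTRUCT":
        raise FormatError(f"{path}: modality {getattr(ds, 'Modality', None)!r} is not RTSTRUCT")
    if "StructureSetROISequence" not in ds or "ROIContourSequence" not in ds:
        raise FormatError(f"{path}: missing ROI/contour sequences")

    names = {int(item.ROINumber): str(item.ROIName) for item in ds.StructureSetROISequence}
    off = (0.0, 0.0, 0.0)
    if isocenter is not None:
        off = (isocenter.lateral_mm, isocenter.vertical_mm, isocenter.longitudinal_mm)

    out: list[StructureSet] = []
    for roi in ds.ROIContourSequence:
        number = int(roi.ReferencedROINumber)
        name = names.get(number, f"ROI_{number}")
        by_z: dict[float, list[np.ndarray]] = {}
        for contour in getattr(roi, "ContourSequence", []):
            data = np.asarray(contour.ContourData, dtype=float).reshape(-1, 3)
            lateral = data[:, 0] - off[0]
            vertical = -data[:, 1] - off[1]
            z = float(np.round(np.mean(data[:, 2]) - off[2], 6))
            poly = np.column_stack([lateral, vertical])
            if len(poly) >= 2 and np.allclose(poly[0], poly[-1]):
                poly = poly[:-1]  # explicit closure in files, implicit in memory
            by_z.setdefault(z, []).append(poly)
        slices = [StructureSlice(z_mm=z, polygons=by_z[z]) for z in sorted(by_z)]
        out.append(StructureSet(name=name, slices=slices))
    return out


def write_rtstruct(
    structures: Sequence[StructureSet],
    path: str | Path,
    ref_geometry: CTGrid | None = None,
    isocenter: Point3 | None = None,
    colors: dict[str, tuple[int, int, int]] | None = None,
    overwrite: bool = False,
) -> None:
    """Write structures to a DICOM RTSTRUCT, preserving names and order.

    ``isocenter`` shifts isocenter-relative contours back to absolute
    coordinates on write; ``colors`` maps structure name to an RGB display
    color (used to paint safe-space ROIs green/red).  Refuses to overwrite
    an existing file unless ``overwrite=True``.
    """
    path = Path(path)
    if not structures:
        raise EmptyStructureError("no structures to write")
    for s in structures:
        if not s.slices:
            raise EmptyStructureError(f"structure {s.name!r} has no slices")
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")

    off = (0.0, 0.0, 0.0)
    if isocenter is not None:
        off = (isocenter.lateral_mm, isocenter.vertical_mm, isocenter.longitudinal_mm)

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = RTSTRUCT_SOP_CLASS
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = RTSTRUCT_SOP_CLASS
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTSTRUCT"
    ds.PatientName = "PHANTOM"
    ds.PatientID = "PHANTOM"
    ds.StudyInstanceUID = generate_uid()
    ds.SeriesInstanceUID = generate_uid()
    ds.StructureSetLabel = "linacclear"
    frame_uid = generate_uid()
    ds.FrameOfReferenceUID = frame_uid

    ref = Dataset()
    ref.FrameOfReferenceUID = frame_uid
    ds.ReferencedFrameOfReferenceSequence = [ref]

    roi_seq, contour_seq, obs_seq = [], [], []
    for i, s in enumerate(structures, start=1):
        item = Dataset()
        item.ROINumber = i
        item.ROIName = s.name
        item.ReferencedFrameOfReferenceUID = frame_uid
        item.ROIGenerationAlgorithm = "AUTOMATIC"
        roi_seq.append(item)

        rc = Dataset()
        rc.ReferencedROINumber = i
        rc.ROIDisplayColor = list((colors or {}).get(s.name, (255, 255, 0)))
        contours = []
        for sl in s.slices:
            for poly in sl.polygons:
                p = np.asarray(poly, dtype=float)
                closed = np.vstack([p, p[:1]])  # explicit closure on disk
                pts = _patient_to_dicom(
                    closed[:, 0] + off[0], closed[:, 1] + off[1], sl.z_mm + off[2]
                )
                c = Dataset()
                c.ContourGeometricType = "CLOSED_PLANAR"
                c.NumberOfContourPoints = len(closed)
                c.ContourData = [f"{v:.6f}" for v in pts.ravel()]
                contours.append(c)
        rc.ContourSequence = contours
        contour_seq.append(rc)

        ob = Dataset()
        ob.ObservationNumber = i
        ob.ReferencedROINumber = i
        ob.RTROIInterpretedType = ""
        ob.ROIInterpreter = ""
        obs_seq.append(ob)

    ds.StructureSetROISequence = roi_seq
    ds.ROIContourSequence = contour_seq
    ds.RTROIObservationsSequence = obs_seq
    if ref_geometry is not None:
        ds.SliceThickness = ref_geometry.spacing_mm[0]
    ds.save_as(str(path), enforce_file_format=True)


# --------------------------------------------------------------------------
# plan specs


def _field_from_mapping(data: dict, index: int) -> BeamField:
    try:
        start = float(data["gantry_start_deg"])
        stop = float(data["gantry_stop_deg"])
    except KeyError as exc:
        raise FormatError(f"field entry missing key {exc}") from exc
    if str(data.get("sweep", "increasing")) == "decreasing":
        start, stop = stop, start
    arc = AngleInterval(start, stop)
    if data.get("full_arc"):
        arc = AngleInterval.full()
    return BeamField(
        name=str(data.get("name", f"field_{index + 1}")),
        couch_angle_deg=float(data.get("couch_angle_deg", 0.0)),
        arc=arc,
        order_index=int(data.get("order_index", index)),
    )


def load_plan(path: str | Path) -> PlanSpec:
    """Load a plan spec from YAML or JSON.

    Expected layout::

        isocenter_mm: {lateral: 0.0, vertical: -40.0, longitudinal: 0.0}
        fields:
          - name: arc1
            couch_angle_deg: 0.0
            gantry_start_deg: -180.0
            gantry_stop_deg: 180.0   # swept in increasing-angle direction
    """
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if not isinstance(data, dict) or "isocenter_mm" not in data or "fields" not in data:
        raise FormatError(f"{path}: plan spec needs isocenter_mm and fields")
    iso = data["isocenter_mm"]
    isocenter = Point3(
        lateral_mm=float(iso.get("lateral", 0.0)),
        vertical_mm=float(iso.get("vertical", 0.0)),
        longitudinal_mm=float(iso.get("longitudinal", 0.0)),
    )
    fields = tuple(
        _field_from_mapping(f, i) for i, f in enumerate(data["fields"])
    )
    return PlanSpec(isocenter=isocenter, fields=fields)


def save_plan(plan: PlanSpec, path: str | Path) -> None:
    data = {
        "isocenter_mm": {
            "lateral": plan.isocenter.lateral_mm,
            "vertical": plan.isocenter.vertical_mm,
            "longitudinal": plan.isocenter.longitudinal_mm,
        },
        "fields": [
            {
                "name": f.name,
                "couch_angle_deg": f.couch_angle_deg,
                "gantry_start_deg": f.arc.start_deg,
                "gantry_stop_deg": f.arc.end_deg,
                "order_index": f.order_index,
                **({"full_arc": True} if f.arc.is_full else {}),
            }
            for f in plan.fields
        ],
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_rtplan(path: str | Path) -> PlanSpec:
    """Thin adapter pulling isocenter, couch angle and gantry arc from a DICOM RTPLAN.

    Only the subset needed for clearance checking is read: the first control
    point's isocenter, patient-support (couch) angle and gantry angle, plus
    the final control point's gantry angle and rotation direction.
    """
    try:
        ds = pydicom.dcmread(str(path))
    except Exception as exc:
        raise FormatError(f"{path}: not a readable DICOM file ({exc})") from exc
    if "BeamSequence" not in ds:
        raise FormatError(f"{path}: no BeamSequence")
    fields = []
    isocenter = None
    for i, beam in enumerate(ds.BeamSequence):
        cps = beam.ControlPointSequence
        first, last = cps[0], cps[-1]
        if isocenter is None and "IsocenterPosition" in first:
            x, y, z = (float(v) for v in first.IsocenterPosition)
            isocenter = Point3(lateral_mm=x, vertical_mm=-y, longitudinal_mm=z)
        couch = float(getattr(first, "PatientSupportAngle", 0.0))
        couch = couch - 360.0 if couch > 180.0 else couch
        start = float(getattr(first, "GantryAngle", 0.0))
        stop = float(getattr(last, "GantryAngle", start))
        direction = str(getattr(first, "GantryRotationDirection", "CW"))
        if direction == "CC":
            start, stop = stop, start
        fields.append(
            BeamField(
                name=str(getattr(beam, "BeamName", f"beam_{i + 1}")),
                couch_angle_deg=couch,
                arc=AngleInterval(start, stop),
                order_index=i,
            )
        )
    if isocenter is None:
        isocenter = Point3(0.0, 0.0, 0.0)
    return PlanSpec(isocenter=isocenter, fields=tuple(fields))


# --------------------------------------------------------------------------
# CT body contouring and couch model


def body_from_ct(
    grid: CTGrid,
    threshold_gcc: float = 0.6,
    min_area_mm2: float = 500.0,
    name: str = "BODY",
) -> StructureSet:
    """Auto-contour the patient body from a density grid.

    Each slice is thresholded at ``threshold_gcc`` (the conventional
    body/air cut at 0.6 g/cm^3) and traced with marching squares; the
    largest closed boundary per slice is kept, plus any further component
    enclosing more than ``min_area_mm2``.
    """
    if not np.any(grid.density >= threshold_gcc):
        raise EmptyBodyError(f"no voxel reaches {threshold_gcc} g/cm^3")
    dz, dv, dl = grid.spacing_mm
    z0, v0, l0 = grid.origin_mm
    slices = []
    for iz in range(grid.density.shape[0]):
        mask = (grid.density[iz] >= threshold_gcc).astype(float)
        if not mask.any():
            continue
        padded = np.pad(mask, 1, constant_values=0.0)
        contours = measure.find_contours(padded, 0.5)
        polys = []
        for c in contours:
            rows = c[:, 0] - 1.0  # undo padding
            cols = c[:, 1] - 1.0
            lateral = l0 + cols * dl
            vertical = v0 + rows * dv
            poly = np.column_stack([lateral, vertical])
            if len(poly) >= 2 and np.allclose(poly[0], poly[-1]):
                poly = poly[:-1]
            if len(poly) >= 3 and polygon_area_mm2(poly) > 0:
                polys.append(poly)
        if not polys:
            continue
        polys.sort(key=polygon_area_mm2, reverse=True)
        kept = [polys[0]] + [p for p in polys[1:] if polygon_area_mm2(p) >= min_area_mm2]
        slices.append(StructureSlice(z_mm=z0 + iz * dz, polygons=kept))
    if not slices:
        raise EmptyBodyError("thresholding produced no usable contours")
    return StructureSet(name=name, slices=slices)


def build_couch_structure(
    kind: str,
    top_height_mm: float,
    width_mm: float,
    thickness_mm: float,
    z_range_mm: tuple[float, float],
    plate_thickness_mm: float | None = None,
    plate_width_mm: float | None = None,
    slice_spacing_mm: float = 10.0,
    lateral_center_mm: float = 0.0,
    name: str = "COUCH",
) -> StructureSet:
    """Parametric couch: a rectangular slab per slice, optionally with a prone plate.

    ``top_height_mm`` is the vertical coordinate of the couch top (negative
    = below isocenter); the slab spans ``[top - thickness, top]``.  The
    ``prone_plate`` kind adds a raised slab of ``plate_thickness_mm`` above
    the couch top, emulating a thick prone positioning plate.
    """
    if kind not in ("flat", "prone_plate"):
        raise InvalidGeometryError(f"unknown couch kind {kind!r}")
    if thickness_mm <= 0 or width_mm <= 0:
        raise InvalidGeometryError("couch width and thickness must be > 0")
    if kind == "prone_plate":
        if plate_thickness_mm is None or plate_thickness_mm <= 0:
            raise InvalidGeometryError("prone_plate requires plate_thickness_mm > 0")
    z_lo, z_hi = z_range_mm
    zs = np.arange(z_lo, z_hi + 0.5 * slice_spacing_mm, slice_spacing_mm)
    if len(zs) < 1 or z_hi < z_lo:
        raise EmptyStructureError("couch z range spans no slices")

    hw = 0.5 * width_mm
    cl = lateral_center_mm

    def rect(half_width: float, bottom: float, top: float) -> np.ndarray:
        return np.array(
            [
                [cl - half_width, bottom],
                [cl + half_width, bottom],
                [cl + half_width, top],
                [cl - half_width, top],
            ]
        )

    slices = []
    for z in zs:
        polys = [rect(hw, top_height_mm - thickness_mm, top_height_mm)]
        if kind == "prone_plate":
            phw = 0.5 * (plate_width_mm if plate_width_mm is not None else width_mm)
            polys.append(rect(phw, top_height_mm, top_height_mm + plate_thickness_mm))
        slices.append(StructureSlice(z_mm=float(z), polygons=polys))
    return StructureSet(name=name, slices=slices)
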