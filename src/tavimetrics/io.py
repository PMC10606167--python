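"""I/O for every external artifact: meshes, landmarks, measurement reports.

All geometry is millimetres in the LPS (left-posterior-superior) world
frame.  Units and frame are declared, never inferred — no RAS/LPS auto-flip
is ever applied, because a silent frame conversion is the classic failure
mode in medical-image geometry.
"""

from __future__ import annotations

import csv
import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import trimesh

from .errors import FormatError, SchemaError, ValidationError

__all__ = [
    "LandmarkSet",
    "SectionMeasurements",
    "SntjMeasurements",
    "SovMeasurements",
    "CoronaryMeasurements",
    "MeasurementReport",
    "read_mesh",
    "write_mesh",
    "validate_mesh",
    "read_landmarks",
    "write_landmarks",
    "write_report",
    "read_report",
]

LANDMARK_NAMES = (
    "left_coronary_ostium",
    "right_coronary_ostium",
    "nadir_left",
    "nadir_right",
    "nadir_noncoronary",
)

_MESH_FORMATS = ("STL", "PLY", "OBJ", "VTP")


# --------------------------------------------------------------------------
# landmarks
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LandmarkSet:
    """The five anatomical points driving every measurement plane.

    Three leaflet nadirs (left-, right-, non-coronary) define the annulus
    plane; the two coronary ostia give the coronary heights.  Points are mm,
    LPS.
    """

    left_coronary_ostium: np.ndarray
    right_coronary_ostium: np.ndarray
    nadir_left: np.ndarray
    nadir_right: np.ndarray
    nadir_noncoronary: np.ndarray

    def __post_init__(self):
        for f in fields(self):
            p = np.asarray(getattr(self, f.name), dtype=float)
            if p.shape != (3,):
                raise ValidationError(f"landmark {f.name!r} must be a 3-vector")
            if not np.all(np.isfinite(p)):
                raise ValidationError(f"landmark {f.name!r} has non-finite values")
            object.__setattr__(self, f.name, p)
        # collinear nadirs leave the annulus plane undefined
        if self.nadir_triangle_area() < 1e-6:
            raise ValidationError("the three nadirs are collinear; no annulus plane")

    def nadirs(self) -> np.ndarray:
        """(3, 3) array of the nadirs, ordered left, right, non-coronary."""
        return np.vstack([self.nadir_left, self.nadir_right, self.nadir_noncoronary])

    def nadir_centroid(self) -> np.ndarray:
        return self.nadirs().mean(axis=0)

    def nadir_triangle_area(self) -> float:
        a, b, c = self.nadirs()
        return 0.5 * float(np.linalg.norm(np.cross(b - a, c - a)))

    def as_dict(self) -> dict[str, list[float]]:
        return {name: list(map(float, getattr(self, name))) for name in LANDMARK_NAMES}

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "LandmarkSet":
        """Apply a rigid transform x → R·x + t to all five points."""
        return LandmarkSet(**{
            name: rotation @ getattr(self, name) + translation
            for name in LANDMARK_NAMES
        })


def read_landmarks(path) -> LandmarkSet:
    """Read the landmark JSON file: the five named keys, each [x, y, z] mm LPS.

    An optional ``"frame"`` key, if present, must equal ``"LPS"``.
    """
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise FormatError(f"{path}: not valid JSON: {e}") from e
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: top level must be a JSON object")
    frame = data.pop("frame", "LPS")
    if frame != "LPS":
        raise SchemaError(f"{path}: frame must be 'LPS', got {frame!r}")
    for name in LANDMARK_NAMES:
        if name not in data:
            raise SchemaError(f"{path}: missing landmark key {name!r}")
    unknown = set(data) - set(LANDMARK_NAMES)
    if unknown:
        raise SchemaError(f"{path}: unknown keys {sorted(unknown)}")
    return LandmarkSet(**{name: np.asarray(data[name], dtype=float)
                          for name in LANDMARK_NAMES})


def write_landmarks(lm: LandmarkSet, path) -> None:
    payload = {"frame": "LPS", **lm.as_dict()}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


# --------------------------------------------------------------------------
# meshes
# --------------------------------------------------------------------------

def validate_mesh(mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    """Check the closed-orientable-2-manifold invariant.

    Multiple connected components are accepted (the aortic root and LV may
    arrive as separate shells); every edge of every component must be shared
    by exactly two faces.
    """
    if len(mesh.vertices) == 0 or len(mesh.faces) == 0:
        raise ValidationError("mesh has no geometry")
    if not np.all(np.isfinite(mesh.vertices)):
        raise ValidationError("mesh vertices contain non-finite coordinates")
    if mesh.faces.max() >= len(mesh.vertices):
        raise ValidationError("face index out of range")
    edges = mesh.edges_sorted
    _, counts = np.unique(edges, axis=0, return_counts=True)
    bad = int(np.sum(counts != 2))
    if bad:
        raise ValidationError(
            f"mesh is not a closed 2-manifold: {bad} edges not shared by "
            "exactly 2 faces"
        )
    return mesh


def read_mesh(path, fmt: str | None = None) -> trimesh.Trimesh:
    """Read a surface mesh (STL/PLY/OBJ/VTP) and validate it.

    Coordinates are taken as mm in LPS; no conversion is applied.  Attribute
    data (normals, colors) is discarded — only geometry feeds the pipeline.
    """
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).upper()
    if fmt not in _MESH_FORMATS:
        raise FormatError(f"unsupported mesh format {fmt!r}; "
                          f"expected one of {_MESH_FORMATS}")
    if not path.exists():
        raise FormatError(f"mesh file not found: {path}")
    if fmt == "VTP":
        vertices, faces = _read_vtp(path)
        mesh = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    else:
        try:
            loaded = trimesh.load(path, file_type=fmt.lower(), force="mesh",
                                  process=False)
        except Exception as e:
            raise FormatError(f"{path}: failed to parse as {fmt}: {e}") from e
        if not isinstance(loaded, trimesh.Trimesh) or len(loaded.faces) == 0:
            raise FormatError(f"{path}: no triangle geometry found")
        mesh = trimesh.Trimesh(vertices=np.asarray(loaded.vertices, dtype=float),
                               faces=np.asarray(loaded.faces, dtype=int),
                               process=False)
    # merge exactly coincident vertices so STL triangle soups regain their
    # shared-edge topology, without any geometric tolerance
    mesh.merge_vertices(merge_tex=True, merge_norm=True)
    return validate_mesh(mesh)


def write_mesh(mesh: trimesh.Trimesh, path, fmt: str | None = None) -> None:
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).upper()
    if fmt not in _MESH_FORMATS:
        raise FormatError(f"unsupported mesh format {fmt!r}")
    if fmt == "VTP":
        _write_vtp(mesh, path)
    else:
        mesh.export(path, file_type=fmt.lower())


def _read_vtp(path: Path) -> tuple[np.ndarray, np.ndarray]:
    """Minimal reader for ASCII VTK XML PolyData (points + triangle polys)."""
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as e:
        raise FormatError(f"{path}: not valid VTP XML: {e}") from e
    piece = root.find(".//Piece")
    if piece is None:
        raise FormatError(f"{path}: no <Piece> element")
    pts_el = piece.find("./Points/DataArray")
    if pts_el is None or pts_el.get("format", "ascii") != "ascii":
        raise FormatError(f"{path}: only ascii VTP points are supported")
    vertices = np.fromstring(pts_el.text, sep=" ").reshape(-1, 3)
    conn = off = None
    for arr in piece.findall("./Polys/DataArray"):
        if arr.get("Name") == "connectivity":
            conn = np.fromstring(arr.text, sep=" ", dtype=float).astype(int)
        elif arr.get("Name") == "offsets":
            off = np.fromstring(arr.text, sep=" ", dtype=float).astype(int)
    if conn is None or off is None:
        raise FormatError(f"{path}: missing Polys connectivity/offsets")
    faces = []
    start = 0
    for end in off:
        poly = conn[start:end]
        if len(poly) != 3:
            raise FormatError(f"{path}: non-triangle polygon with {len(poly)} "
                              "vertices; triangulate before use")
        faces.append(poly)
        start = end
    return vertices, np.asarray(faces, dtype=int)


def _write_vtp(mesh: trimesh.Trimesh, path: Path) -> None:
    v = np.asarray(mesh.vertices, dtype=float)
    f = np.asarray(mesh.faces, dtype=int)
    pts = "\n".join(" ".join(f"{x:.9g}" for x in row) for row in v)
    conn = "\n".join(" ".join(str(i) for i in row) for row in f)
    offs = " ".join(str(3 * (i + 1)) for i in range(len(f)))
    path.write_text(f"""<?xml version="1.0"?>
<VTKFile type="PolyData" version="0.1" byte_order="LittleEndian">
  <PolyData>
    <Piece NumberOfPoints="{len(v)}" NumberOfPolys="{len(f)}">
      <Points>
        <DataArray type="Float64" NumberOfComponents="3" format="ascii">
{pts}
        </DataArray>
      </Points>
      <Polys>
        <DataArray type="Int64" Name="connectivity" format="ascii">
{conn}
        </DataArray>
        <DataArray type="Int64" Name="offsets" format="ascii">
{offs}
        </DataArray>
      </Polys>
    </Piece>
  </PolyData>
</VTKFile>
""")


# --------------------------------------------------------------------------
# measurement report
# --------------------------------------------------------------------------

@dataclass
class SectionMeasurements:
    """Full cross-section metric set (annulus and LVOT)."""

    area: float              # mm²
    perimeter: float         # mm
    diameter_min: float      # mm
    diameter_max: float      # mm
    diameter_avg: float      # mm, (min + max)/2
    diameter_area_derived: float    # mm, 2·√(area/π)
    diameter_perimeter_derived: float  # mm, perimeter/π


@dataclass
class SntjMeasurements:
    diameter_min: float
    diameter_max: float
    diameter_avg: float


@dataclass
class SovMeasurements:
    """Per-sinus diameters at the sinus-of-Valsalva plane."""

    diameter_lcc: float
    diameter_rcc: float
    diameter_ncc: float


@dataclass
class CoronaryMeasurements:
    height_left: float
    height_right: float


@dataclass
class MeasurementReport:
    """The 22 scalar measurements of the aortic valvular complex.

    7 annulus + 7 LVOT + 3 SNTJ + 3 sinus + 2 coronary heights = 22, all mm
    or mm².  ``metadata`` carries input identifiers, the effective parameter
    values and any QC flags raised during the run.
    """

    annulus: SectionMeasurements
    lvot: SectionMeasurements
    sntj: SntjMeasurements
    sov: SovMeasurements
    coronary: CoronaryMeasurements
    metadata: dict = field(default_factory=dict)

    def flat(self) -> dict[str, float]:
        """Ordered {region.name: value} mapping of the 22 measurements."""
        out: dict[str, float] = {}
        for region in ("annulus", "lvot", "sntj", "sov", "coronary"):
            block = getattr(self, region)
            for f in fields(block):
                out[f"{region}.{f.name}"] = float(getattr(block, f.name))
        return out

    def validate(self) -> None:
        values = self.flat()
        if len(values) != 22:
            raise ValidationError(f"report has {len(values)} fields, expected 22")
        for name, v in values.items():
            if not np.isfinite(v):
                raise ValidationError(f"measurement {name} is not finite")
        for region in ("annulus", "lvot"):
            block = getattr(self, region)
            if block.area <= 0 or block.perimeter <= 0:
                raise ValidationError(f"{region}: area and perimeter must be > 0")
            if not (block.diameter_min <= block.diameter_avg <= block.diameter_max):
                raise ValidationError(f"{region}: diameter ordering violated")
            if block.diameter_area_derived > block.diameter_perimeter_derived * (1 + 1e-9):
                raise ValidationError(
                    f"{region}: isoperimetric inequality violated "
                    "(d_area > d_perimeter)")
        if not (self.sntj.diameter_min <= self.sntj.diameter_avg
                <= self.sntj.diameter_max):
            raise ValidationError("sntj: diameter ordering violated")

    def to_dict(self) -> dict:
        return {
            "annulus": vars(self.annulus).copy(),
            "lvot": vars(self.lvot).copy(),
            "sntj": vars(self.sntj).copy(),
            "sov": vars(self.sov).copy(),
            "coronary": vars(self.coronary).copy(),
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MeasurementReport":
        try:
            return cls(
                annulus=SectionMeasurements(**d["annulus"]),
                lvot=SectionMeasurements(**d["lvot"]),
                sntj=SntjMeasurements(**d["sntj"]),
                sov=SovMeasurements(**d["sov"]),
                coronary=CoronaryMeasurements(**d["coronary"]),
                metadata=d.get("metadata", {}),
            )
        except (KeyError, TypeError) as e:
            raise SchemaError(f"malformed report dictionary: {e}") from e


def write_report(report: MeasurementReport, path, fmt: str | None = None) -> None:
    """Write a report as nested JSON or as CSV with columns name,value,units.

    The CSV has exactly one row per measurement (22 rows).  A report with a
    non-finite field is refused.
    """
    report.validate()
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).upper()
    if fmt == "JSON":
        path.write_text(json.dumps(report.to_dict(), indent=2) + "\n")
    elif fmt == "CSV":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["name", "value", "units"])
            for name, value in report.flat().items():
                units = "mm2" if name.endswith(".area") else "mm"
                writer.writerow([name, repr(value), units])
    else:
        raise FormatError(f"unsupported report format {fmt!r}; use JSON or CSV")


def read_report(path) -> MeasurementReport:
    """Read back a JSON report (lossless round-trip of write_report)."""
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise FormatError(f"{path}: not valid JSON: {e}") from e
    return MeasurementReport.from_dict(data)
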