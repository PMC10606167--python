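"""Anatomical planes and the 22-measurement report.

This is the measurement-derivation core: from a validated mesh, the five
landmarks and a centerline it constructs the annulus, LVOT, sinus-of-
Valsalva (SOV) and sinotubular-junction (SNTJ) planes, measures every
cross-section, and assembles the full report:

* annulus — area, perimeter, min/max/avg diameter, area-/perimeter-derived
  diameter (7);
* LVOT, on the plane 4 mm below the annulus along the centerline (7);
* SNTJ — min/max/avg diameter (3);
* SOV — one diameter per sinus, named by its nadir (3);
* coronary heights, left and right (2).
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import trimesh

from .centerline import (
    Centerline,
    LBCParams,
    extract_centerline_lbc,
    orient_centerline,
)
from .cross_section import (
    CrossSection,
    Plane,
    ProfileStation,
    area_profile,
    derived_diameters,
    min_max_diameters,
    slice_mesh,
)
from .errors import GeometryError, StageError, ValidationError
from .io import (
    CoronaryMeasurements,
    LandmarkSet,
    MeasurementReport,
    SectionMeasurements,
    SntjMeasurements,
    SovMeasurements,
    validate_mesh,
)

__all__ = [
    "PipelineConfig",
    "PlaneSet",
    "SinusDiameters",
    "annulus_plane",
    "lvot_plane",
    "find_sov_sntj",
    "sinus_diameters",
    "coronary_height",
    "section_measurements",
    "run_pipeline",
]

log = logging.getLogger(__name__)

_MIN_NADIR_TRIANGLE_MM2 = 1.0


@dataclass
class PipelineConfig:
    """Every tunable of the measurement pipeline, with its default.

    The defaults are the documented operating point: planes every 1 mm
    along the centerline, the LVOT 4 mm below the annulus, 0.5° chord scan,
    SNTJ plateau detection at 2% relative area change over 3 consecutive
    stations, and an anatomical 40 mm cap on the SOV search.
    """

    plane_spacing_mm: float = 1.0
    lvot_offset_mm: float = 4.0
    angular_step_deg: float = 0.5
    sntj_rel_tol: float = 0.02
    sntj_window: int = 3
    sov_search_max_mm: float = 40.0
    orientation_mode: str = "tangent"   # or "annulus_parallel"
    allow_partial: bool = False
    centerline: LBCParams = field(default_factory=LBCParams)

    def __post_init__(self):
        if isinstance(self.centerline, dict):
            self.centerline = LBCParams(**self.centerline)
        if self.plane_spacing_mm <= 0:
            raise ValidationError("plane_spacing_mm must be positive")
        if self.lvot_offset_mm < 0:
            raise ValidationError("lvot_offset_mm must be non-negative")
        if self.orientation_mode not in ("tangent", "annulus_parallel"):
            raise ValidationError(
                f"unknown orientation_mode {self.orientation_mode!r}")
        if self.sntj_window < 1:
            raise ValidationError("sntj_window must be >= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PlaneSet:
    """The four anatomical planes, with the SOV/SNTJ centerline stations."""

    annulus: Plane
    lvot: Plane
    sov: Plane
    sntj: Plane
    s_annulus: float
    s_sov: float
    s_sntj: float


@dataclass
class SinusDiameters:
    """Per-sinus diameters at the SOV plane, with the contour intersection
    points retained for QC overlays."""

    lcc: float
    rcc: float
    ncc: float
    endpoints: dict[str, np.ndarray] = field(default_factory=dict)


def annulus_plane(nadirs: np.ndarray, cl: Centerline) -> Plane:
    """Plane through the three leaflet nadirs.

    Origin is the nadir centroid; the normal is the unit normal of the
    nadir triangle with its sign chosen to point toward increasing
    centerline arc length, i.e. toward the ascending aorta.

    Raises a GeometryError (QC: "nadir geometry implausible") when the
    nadir triangle is nearly degenerate — the classic signature of a failed
    nadir detection.
    """
    nadirs = np.asarray(nadirs, dtype=float)
    if nadirs.shape != (3, 3):
        raise ValidationError("annulus_plane needs exactly 3 nadir points")
    a, b, c = nadirs
    normal = np.cross(b - a, c - a)
    area = 0.5 * float(np.linalg.norm(normal))
    if area < _MIN_NADIR_TRIANGLE_MM2:
        raise GeometryError(
            f"nadir geometry implausible: nadir triangle area {area:.3g} mm² "
            f"< {_MIN_NADIR_TRIANGLE_MM2} mm²")
    normal = normal / np.linalg.norm(normal)
    origin = nadirs.mean(axis=0)
    s_ann = cl.closest_s(origin)
    if np.dot(normal, cl.tangent_at(s_ann)) < 0:
        normal = -normal
    return Plane(origin=origin, normal=normal)


def lvot_plane(annulus: Plane, cl: Centerline, offset: float = 4.0) -> Plane:
    """LVOT plane: the annulus plane translated ``offset`` mm down the
    centerline, keeping the annulus normal.

    The shift is a pure translation, not a re-orientation: the LVOT plane
    inherits the annulus orientation exactly, which is why a nadir error
    propagates into every LVOT measurement.
    """
    s_ann = cl.closest_s(annulus.origin)
    s_lvot = s_ann - offset
    if s_lvot < 0:
        raise ValidationError(
            f"centerline has only {s_ann:.1f} mm below the annulus; cannot "
            f"shift by {offset} mm")
    return Plane(origin=cl.point_at(s_lvot), normal=annulus.normal)


def find_sov_sntj(profile: list[ProfileStation], s_annulus: float,
                  rel_tol: float = 0.02, window: int = 3,
                  qc_flags: list[str] | None = None) -> tuple[float, float]:
    """Locate the SOV and SNTJ stations on the area profile.

    The SOV is the station of greatest cross-sectional area above the
    annulus (ties resolve to the smallest s).  The SNTJ is where the area
    "stabilizes": the smallest s > s_sov whose relative area change stays
    below ``rel_tol`` for ``window`` consecutive inter-station steps.  If no
    station satisfies that, the station of minimum |dA/ds| above the SOV is
    used and a QC flag recorded.  An SOV at either profile boundary is
    flagged too — it usually means the bulge was missed.
    """
    qc = qc_flags if qc_flags is not None else []
    valid = [st for st in profile if not st.missing and st.s >= s_annulus]
    if len(valid) < max(window + 2, 4):
        raise GeometryError(
            f"area profile has only {len(valid)} valid stations above the "
            "annulus; cannot search for SOV/SNTJ")
    s_arr = np.array([st.s for st in valid])
    a_arr = np.array([st.area for st in valid])

    i_sov = int(np.argmax(a_arr))
    if i_sov in (0, len(valid) - 1):
        qc.append("SOV at search boundary")
        s_sov = float(s_arr[i_sov])
    else:
        # sub-station refinement: parabola through the argmax and its two
        # neighbours.  The 1 mm profile grid localizes the peak only to a
        # station, but on the bulge flanks the radius changes fast enough
        # that the per-sinus diameters need the true apex.
        a0, a1, a2 = a_arr[i_sov - 1:i_sov + 2]
        denom = a0 - 2 * a1 + a2
        shift = 0.0 if abs(denom) < 1e-12 else 0.5 * (a0 - a2) / denom
        shift = float(np.clip(shift, -0.5, 0.5))
        ds = s_arr[i_sov + 1] - s_arr[i_sov]
        s_sov = float(s_arr[i_sov] + shift * ds)

    rel = np.abs(np.diff(a_arr)) / a_arr[:-1]  # rel[i] = change from station i
    s_sntj = None
    for i in range(i_sov + 1, len(valid) - window):
        if np.all(rel[i:i + window] < rel_tol):
            s_sntj = float(s_arr[i])
            break
    if s_sntj is None:
        after = rel[i_sov + 1:]
        if after.size == 0:
            raise GeometryError("no stations above the SOV to place the SNTJ")
        s_sntj = float(s_arr[i_sov + 1 + int(np.argmin(after))])
        qc.append("SNTJ stabilization not reached; used minimum |dA/ds|")
    return s_sov, s_sntj


def sinus_diameters(sov_section: CrossSection, landmarks: LandmarkSet,
                    qc_flags: list[str] | None = None) -> SinusDiameters:
    """Per-sinus diameters on the SOV section.

    Each nadir is orthogonally projected onto the SOV plane; the full line
    through that projection and the section centroid is intersected with
    the contour, and the sinus diameter is the distance between the two
    boundary crossings.  Diameters are named lcc/rcc/ncc after the left-,
    right- and non-coronary nadirs.

    A line crossing the contour more (or fewer) than twice takes the two
    crossings farthest apart on opposite sides of the centroid, with a
    "non-convex sinus contour" QC flag.
    """
    qc = qc_flags if qc_flags is not None else []
    plane = sov_section.plane
    coords2d = sov_section.coords2d
    c2 = sov_section.centroid2d

    out: dict[str, float] = {}
    endpoints: dict[str, np.ndarray] = {}
    for label, nadir in (("lcc", landmarks.nadir_left),
                         ("rcc", landmarks.nadir_right),
                         ("ncc", landmarks.nadir_noncoronary)):
        p2 = plane.to_plane_coords(nadir)[0]
        d = p2 - c2
        dist = float(np.linalg.norm(d))
        if dist < 0.1:
            raise GeometryError(
                f"{label}: projected nadir within {dist:.3f} mm of the "
                "section centroid; sinus line direction undefined")
        d = d / dist
        ts = _line_contour_crossings(coords2d, c2, d)
        pos = ts[ts > 0]
        neg = ts[ts < 0]
        if pos.size == 0 or neg.size == 0:
            raise GeometryError(
                f"{label}: sinus line does not cross the contour on both "
                "sides of the centroid")
        if pos.size != 1 or neg.size != 1:
            qc.append(f"non-convex sinus contour ({label})")
        t_hi, t_lo = float(pos.max()), float(neg.min())
        out[label] = t_hi - t_lo
        endpoints[label] = plane.from_plane_coords(
            np.vstack([c2 + t_hi * d, c2 + t_lo * d]))
    return SinusDiameters(lcc=out["lcc"], rcc=out["rcc"], ncc=out["ncc"],
                          endpoints=endpoints)


def _line_contour_crossings(coords2d: np.ndarray, point: np.ndarray,
                            direction: np.ndarray) -> np.ndarray:
    """Signed parameters t of every crossing of line point + t·direction
    with the closed polygon ``coords2d``."""
    p0 = coords2d
    p1 = np.roll(coords2d, -1, axis=0)
    edge = p1 - p0
    rel = p0 - point
    denom = direction[0] * edge[:, 1] - direction[1] * edge[:, 0]
    ok = np.abs(denom) > 1e-14
    t = (rel[:, 0] * edge[:, 1] - rel[:, 1] * edge[:, 0])[ok] / denom[ok]
    u = (rel[:, 0] * direction[1] - rel[:, 1] * direction[0])[ok] / denom[ok]
    return t[(u >= 0.0) & (u < 1.0)]


def coronary_height(ostium: np.ndarray, annulus: Plane) -> float:
    """Signed perpendicular height of a coronary ostium above the annulus
    plane: (ostium − origin)·normal, positive on the aortic side."""
    ostium = np.asarray(ostium, dtype=float)
    if ostium.shape != (3,) or not np.all(np.isfinite(ostium)):
        raise ValidationError("ostium must be a finite 3-vector")
    return float(np.dot(ostium - annulus.origin, annulus.normal))


def section_measurements(section: CrossSection,
                         angular_step: float = 0.5) -> SectionMeasurements:
    """The seven scalar metrics of one cross-section."""
    d_min, d_max, _, _ = min_max_diameters(section, angular_step=angular_step)
    d_area, d_perim = derived_diameters(section.area, section.perimeter)
    return SectionMeasurements(
        area=section.area,
        perimeter=section.perimeter,
        diameter_min=d_min,
        diameter_max=d_max,
        diameter_avg=0.5 * (d_min + d_max),
        diameter_area_derived=d_area,
        diameter_perimeter_derived=d_perim,
    )


def run_pipeline(mesh: trimesh.Trimesh, landmarks: LandmarkSet,
                 config: PipelineConfig | None = None,
                 centerline: Centerline | None = None,
                 metadata: dict | None = None) -> MeasurementReport:
    """Execute the full measurement pipeline on one case.

    Stages: centerline extraction → annulus plane and section → LVOT plane
    and section → area profile above the annulus → SOV/SNTJ planes, SNTJ
    diameters and per-sinus diameters → coronary heights.  Every stage
    failure is re-raised as a :class:`StageError` tagged with the stage
    name.  The run is deterministic for fixed inputs and config.

    ``centerline`` may be supplied to skip extraction (e.g. when comparing
    extractors); it is oriented by the nadir centroid either way.
    """
    config = config or PipelineConfig()
    qc: list[str] = []
    partial_stages: list[str] = []

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as e:
            raise StageError(name, e) from e

    def optional_stage(name, fn, *args, **kwargs):
        """Like stage(), but under allow_partial a failure yields None and a
        QC record instead of aborting the case."""
        try:
            return fn(*args, **kwargs)
        except Exception as e:
            if not config.allow_partial:
                raise StageError(name, e) from e
            partial_stages.append(name)
            qc.append(f"stage {name} failed: {e}")
            return None

    stage("validate_mesh", validate_mesh, mesh)

    if centerline is None:
        centerline = stage("centerline", extract_centerline_lbc, mesh,
                           config.centerline)
    cl, s_ann = orient_centerline(centerline, landmarks.nadir_centroid())
    log.info("centerline: %.1f mm, annulus at s=%.1f", cl.length, s_ann)

    ann_plane = stage("annulus_plane", annulus_plane, landmarks.nadirs(), cl)
    ann_section = stage("annulus_section", slice_mesh, mesh, ann_plane,
                        cl.point_at(s_ann))
    ann_meas = stage("annulus_metrics", section_measurements, ann_section,
                     config.angular_step_deg)

    def measure_lvot():
        plane = lvot_plane(ann_plane, cl, config.lvot_offset_mm)
        anchor = cl.point_at(max(s_ann - config.lvot_offset_mm, 0.0))
        section = slice_mesh(mesh, plane, anchor)
        return section_measurements(section, config.angular_step_deg)

    lv_meas = optional_stage("lvot", measure_lvot)

    def locate_root_planes():
        s_hi = min(s_ann + config.sov_search_max_mm, cl.length)
        profile = area_profile(mesh, cl, s_ann, s_hi,
                               config.plane_spacing_mm,
                               config.orientation_mode, ann_plane.normal)
        s_sov, s_sntj = find_sov_sntj(profile, s_ann, config.sntj_rel_tol,
                                      config.sntj_window, qc)
        by_s = {st.s: st for st in profile if not st.missing}
        # the refined SOV station falls between profile stations: cut it
        sov_plane = Plane(origin=cl.point_at(s_sov),
                          normal=cl.tangent_at(s_sov)
                          if config.orientation_mode == "tangent"
                          else ann_plane.normal)
        sov_section = slice_mesh(mesh, sov_plane, cl.point_at(s_sov))
        return s_sov, s_sntj, sov_section, by_s[s_sntj].section

    located = optional_stage("sov_sntj_search", locate_root_planes)
    if located is not None:
        s_sov, s_sntj, sov_section, sntj_section = located
        sntj_res = optional_stage(
            "sntj_metrics", min_max_diameters, sntj_section,
            config.angular_step_deg)
        sinus = optional_stage("sinus_diameters", sinus_diameters,
                               sov_section, landmarks, qc)
    else:
        s_sov = s_sntj = float("nan")
        sntj_res = sinus = None
    sntj_min, sntj_max = (sntj_res[0], sntj_res[1]) if sntj_res else \
        (float("nan"), float("nan"))

    lch = stage("coronary_height", coronary_height,
                landmarks.left_coronary_ostium, ann_plane)
    rch = stage("coronary_height", coronary_height,
                landmarks.right_coronary_ostium, ann_plane)
    # clinical convention reports positive heights; a non-positive signed
    # value indicates a landmark/plane failure, not anatomy
    for name, h in (("left", lch), ("right", rch)):
        if h <= 0:
            qc.append(f"non-positive {name} coronary height ({h:.2f} mm)")

    nan = float("nan")
    meta = dict(metadata or {})
    meta.update({
        "config": config.to_dict(),
        "qc_flags": qc,
        "s_annulus_mm": float(s_ann),
        "s_sov_mm": float(s_sov),
        "s_sntj_mm": float(s_sntj),
        "centerline_length_mm": float(cl.length),
        "signed_coronary_heights_mm": {"left": lch, "right": rch},
    })
    if partial_stages:
        meta["partial"] = True
        meta["missing_stages"] = partial_stages
    report = MeasurementReport(
        annulus=ann_meas,
        lvot=lv_meas if lv_meas is not None else SectionMeasurements(
            nan, nan, nan, nan, nan, nan, nan),
        sntj=SntjMeasurements(
            diameter_min=sntj_min,
            diameter_max=sntj_max,
            diameter_avg=0.5 * (sntj_min + sntj_max)),
        sov=SovMeasurements(
            diameter_lcc=sinus.lcc if sinus else nan,
            diameter_rcc=sinus.rcc if sinus else nan,
            diameter_ncc=sinus.ncc if sinus else nan),
        coronary=CoronaryMeasurements(height_left=abs(lch),
                                      height_right=abs(rch)),
        metadata=meta,
    )
    if not partial_stages:
        report.validate()
    return report
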