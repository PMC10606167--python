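"""Plane-mesh cross-sections and their scalar metrics.

A measurement plane is intersected with the surface mesh; the anatomically
relevant closed loop is selected by an interior anchor point (normally the
centerline point the plane was seeded from), and the loop is reduced to the
clinical scalars: area, perimeter, centroid, minimum/maximum centroid-chord
diameters, and the area-/perimeter-derived diameters used in annulus sizing.

All coordinates are millimetres in the LPS world frame; areas are mm².
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from shapely.geometry import Point, Polygon

from .errors import (
    DegenerateSectionError,
    EmptySectionError,
    GeometryError,
    ValidationError,
)

__all__ = [
    "Plane",
    "CrossSection",
    "slice_mesh",
    "min_max_diameters",
    "derived_diameters",
    "area_profile",
    "ProfileStation",
    "polygon_area",
    "polygon_perimeter",
    "polygon_centroid",
]

_DEGENERATE_AREA_MM2 = 1.0


@dataclass(frozen=True)
class Plane:
    """An oriented plane: a point on it and a unit normal."""

    origin: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        origin = np.asarray(self.origin, dtype=float)
        normal = np.asarray(self.normal, dtype=float)
        if origin.shape != (3,) or normal.shape != (3,):
            raise ValidationError("plane origin and normal must be 3-vectors")
        norm = float(np.linalg.norm(normal))
        if not np.isfinite(norm) or norm < 1e-12:
            raise ValidationError("plane normal has zero or non-finite length")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "normal", normal / norm)

    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        """In-plane orthonormal basis (u, v) with u × v = normal.

        u is the normalized projection of world +x onto the plane, or of
        world +y when the normal is (anti)parallel to +x.  Any fixed
        convention works — the metrics are basis-invariant — but this one is
        reproducible across runs and platforms.
        """
        n = self.normal
        seed = np.array([1.0, 0.0, 0.0])
        if abs(n[0]) > 0.9:
            seed = np.array([0.0, 1.0, 0.0])
        u = seed - np.dot(seed, n) * n
        u /= np.linalg.norm(u)
        v = np.cross(n, u)
        return u, v

    def to_plane_coords(self, points: np.ndarray) -> np.ndarray:
        """Project world points into the (u, v) in-plane frame (drops the
        out-of-plane component)."""
        u, v = self.basis()
        rel = np.atleast_2d(points) - self.origin
        return np.column_stack([rel @ u, rel @ v])

    def from_plane_coords(self, coords2d: np.ndarray) -> np.ndarray:
        u, v = self.basis()
        coords2d = np.atleast_2d(coords2d)
        return self.origin + np.outer(coords2d[:, 0], u) + np.outer(coords2d[:, 1], v)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.origin) @ self.normal


def polygon_area(coords2d: np.ndarray) -> float:
    """Signed shoelace area of a closed 2D polygon (positive if CCW).

    The polygon is given as vertices without the closing repeat.
    """
    x = coords2d[:, 0]
    y = coords2d[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_perimeter(coords2d: np.ndarray) -> float:
    diffs = np.diff(np.vstack([coords2d, coords2d[:1]]), axis=0)
    return float(np.sum(np.linalg.norm(diffs, axis=1)))


def polygon_centroid(coords2d: np.ndarray) -> np.ndarray:
    """Area centroid of a simple 2D polygon (shoelace moments)."""
    x = coords2d[:, 0]
    y = coords2d[:, 1]
    xn = np.roll(x, -1)
    yn = np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * np.sum(cross)
    if abs(a) < 1e-12:
        raise GeometryError("degenerate polygon: zero area, centroid undefined")
    cx = np.sum((x + xn) * cross) / (6.0 * a)
    cy = np.sum((y + yn) * cross) / (6.0 * a)
    return np.array([cx, cy])


@dataclass
class CrossSection:
    """A closed planar contour cut from the mesh, with its metrics.

    ``contour`` is an ordered (N, 3) loop lying in ``plane`` (closing edge
    implicit), counter-clockwise about the plane normal.  ``centroid`` is the
    area centroid of the planar polygon, in world coordinates.
    """

    contour: np.ndarray
    plane: Plane
    area: float = field(init=False)
    perimeter: float = field(init=False)
    centroid: np.ndarray = field(init=False)

    def __post_init__(self):
        contour = np.asarray(self.contour, dtype=float)
        if contour.ndim != 2 or contour.shape[1] != 3 or len(contour) < 3:
            raise ValidationError("contour must be an (N>=3, 3) array")
        off_plane = np.abs(self.plane.signed_distance(contour))
        if off_plane.max() > 1e-6:
            raise ValidationError(
                f"contour points deviate from the plane by up to "
                f"{off_plane.max():.3g} mm (tolerance 1e-6)"
            )
        coords2d = self.plane.to_plane_coords(contour)
        signed = polygon_area(coords2d)
        if signed < 0:  # enforce CCW about the normal
            contour = contour[::-1].copy()
            coords2d = coords2d[::-1]
            signed = -signed
        self.contour = contour
        self._coords2d = coords2d
        self.area = signed
        self.perimeter = polygon_perimeter(coords2d)
        c2 = polygon_centroid(coords2d)
        self.centroid = self.plane.from_plane_coords(c2)[0]
        self._centroid2d = c2

    @property
    def coords2d(self) -> np.ndarray:
        """Contour in the plane's (u, v) frame."""
        return self._coords2d

    @property
    def centroid2d(self) -> np.ndarray:
        return self._centroid2d

    def as_polygon(self) -> Polygon:
        return Polygon(self._coords2d)


def _closed_loops_2d(mesh: trimesh.Trimesh, plane: Plane):
    """All closed intersection loops of mesh and plane, as 2D vertex arrays
    (closing repeat stripped), paired with their world-space versions."""
    section = mesh.section(plane_origin=plane.origin, plane_normal=plane.normal)
    if section is None:
        return []
    loops = []
    for curve in section.discrete:
        curve = np.asarray(curve, dtype=float)
        if len(curve) < 4 or not np.allclose(curve[0], curve[-1], atol=1e-8):
            continue  # open fragment: plane grazed a boundary/cap edge
        world = curve[:-1]
        loops.append((world, plane.to_plane_coords(world)))
    return loops


def slice_mesh(mesh: trimesh.Trimesh, plane: Plane, anchor: np.ndarray) -> CrossSection:
    """Cut ``mesh`` with ``plane`` and return the lumen cross-section.

    When the plane cuts several closed loops (e.g. aortic root plus a
    coronary stub, or root plus the LV through a curved segment), the loop
    whose interior contains the in-plane projection of ``anchor`` is kept;
    if none contains it, the loop whose centroid is nearest the anchor wins.

    Raises
    ------
    EmptySectionError
        if the plane misses the mesh entirely.
    DegenerateSectionError
        if every loop has area below 1 mm².
    """
    anchor = np.asarray(anchor, dtype=float)
    loops = _closed_loops_2d(mesh, plane)
    if not loops:
        raise EmptySectionError("plane does not intersect the mesh in a closed loop")

    anchor2d = plane.to_plane_coords(anchor)[0]
    candidates = []
    for world, coords2d in loops:
        area = abs(polygon_area(coords2d))
        if area < _DEGENERATE_AREA_MM2:
            continue
        candidates.append((world, coords2d, area))
    if not candidates:
        raise DegenerateSectionError(
            f"all {len(loops)} intersection loops are degenerate (< "
            f"{_DEGENERATE_AREA_MM2} mm²)"
        )

    containing = []
    for world, coords2d, area in candidates:
        if Polygon(coords2d).contains(Point(anchor2d)):
            containing.append((world, coords2d, area))
    if containing:
        # smallest containing loop: innermost boundary around the anchor
        world, _, _ = min(containing, key=lambda t: t[2])
    else:
        world, _, _ = min(
            candidates,
            key=lambda t: float(np.linalg.norm(polygon_centroid(t[1]) - anchor2d)),
        )
    return CrossSection(contour=world, plane=plane)


def _chords_through_point(coords2d: np.ndarray, point: np.ndarray,
                          thetas: np.ndarray) -> np.ndarray:
    """Chord length through ``point`` along each direction θ (radians).

    For each θ the infinite line point + t·(cosθ, sinθ) is intersected with
    every polygon edge; the chord spans the outermost crossings on the two
    sides.  Directions with crossings on only one side return NaN.
    """
    p0 = coords2d
    p1 = np.roll(coords2d, -1, axis=0)
    edge = p1 - p0  # (M, 2)
    rel = p0 - point  # (M, 2)
    out = np.full(len(thetas), np.nan)
    for i, theta in enumerate(thetas):
        d = np.array([np.cos(theta), np.sin(theta)])
        denom = d[0] * edge[:, 1] - d[1] * edge[:, 0]
        ok = np.abs(denom) > 1e-14
        t = (rel[:, 0] * edge[:, 1] - rel[:, 1] * edge[:, 0])[ok] / denom[ok]
        u = (rel[:, 0] * d[1] - rel[:, 1] * d[0])[ok] / denom[ok]
        hit = (u >= 0.0) & (u < 1.0)
        t = t[hit]
        if t.size == 0:
            continue
        pos = t[t > 0]
        neg = t[t < 0]
        if pos.size and neg.size:
            out[i] = pos.max() - neg.min()
    return out


def min_max_diameters(section: CrossSection, angular_step: float = 0.5
                      ) -> tuple[float, float, float, float]:
    """Minimum and maximum diameters through the section centroid.

    Scans chord directions θ ∈ [0°, 180°) at ``angular_step`` degrees; each
    chord passes through the area centroid and spans the contour on both
    sides.  The scan grid is anchored to the contour itself (θ = 0 along
    the direction of the vertex farthest from the centroid), which makes
    the result independent of the world frame — a world-anchored grid
    would shift its phase against the polygon under rotation.  Returns
    ``(d_min, d_max, theta_min, theta_max)`` with angles in degrees
    relative to that anchor; ties resolve to the smaller angle.
    Directions where the chord fails to cross the contour on both sides
    (contour not star-shaped about its centroid) are skipped; if every
    direction fails a GeometryError is raised.
    """
    if not (0.0 < angular_step <= 1.0):
        raise ValidationError("angular_step must be in (0, 1] degrees")
    rel = section.coords2d - section.centroid2d
    far = rel[int(np.argmax(np.einsum("ij,ij->i", rel, rel)))]
    theta0 = np.arctan2(far[1], far[0])
    thetas_deg = np.arange(0.0, 180.0, angular_step)
    chords = _chords_through_point(
        section.coords2d, section.centroid2d,
        theta0 + np.deg2rad(thetas_deg)
    )
    valid = np.isfinite(chords)
    if not valid.any():
        raise GeometryError(
            "no centroid chord crosses the contour on both sides"
        )
    chords_v = chords[valid]
    thetas_v = thetas_deg[valid]
    i_min = int(np.argmin(chords_v))  # argmin/argmax take the first, i.e. smallest θ
    i_max = int(np.argmax(chords_v))
    return (
        float(chords_v[i_min]),
        float(chords_v[i_max]),
        float(thetas_v[i_min]),
        float(thetas_v[i_max]),
    )


def derived_diameters(area: float, perimeter: float) -> tuple[float, float]:
    """Area-derived and perimeter-derived diameters.

    d_area = 2·√(area/π) is the diameter of the circle with the section's
    area; d_perim = perimeter/π the diameter of the circle with its
    perimeter.  By the isoperimetric inequality d_perim ≥ d_area, with
    equality only for a circle.
    """
    if area <= 0 or perimeter <= 0:
        raise ValidationError("area and perimeter must be positive")
    return 2.0 * np.sqrt(area / np.pi), perimeter / np.pi


@dataclass
class ProfileStation:
    """One station of the cross-sectional area profile along the centerline."""

    s: float
    area: float | None
    section: CrossSection | None

    @property
    def missing(self) -> bool:
        return self.section is None


def area_profile(mesh: trimesh.Trimesh, cl, s_start: float, s_end: float,
                 spacing: float = 1.0, orientation_mode: str = "tangent",
                 fixed_normal: np.ndarray | None = None) -> list[ProfileStation]:
    """Cross-sectional area at evenly spaced stations along the centerline.

    Planes sit at the centerline point of each station.  With
    ``orientation_mode='tangent'`` each plane is perpendicular to the local
    centerline tangent (sections stay transverse through a curved root);
    with ``'annulus_parallel'`` all planes share ``fixed_normal``.
    Stations where the plane misses the mesh or cuts only degenerate loops
    are recorded as missing, never fabricated; more than 50% missing raises
    a GeometryError (upstream segmentation/centerline failure).
    """
    if spacing <= 0:
        raise ValidationError("spacing must be positive")
    if orientation_mode not in ("tangent", "annulus_parallel"):
        raise ValidationError(f"unknown orientation_mode {orientation_mode!r}")
    if orientation_mode == "annulus_parallel" and fixed_normal is None:
        raise ValidationError("annulus_parallel mode requires fixed_normal")

    stations = np.arange(s_start, s_end + 1e-9, spacing)
    out: list[ProfileStation] = []
    for s in stations:
        point = cl.point_at(s)
        if orientation_mode == "tangent":
            normal = cl.tangent_at(s)
        else:
            normal = np.asarray(fixed_normal, dtype=float)
        plane = Plane(origin=point, normal=normal)
        try:
            sec = slice_mesh(mesh, plane, anchor=point)
        except (EmptySectionError, DegenerateSectionError):
            out.append(ProfileStation(s=float(s), area=None, section=None))
            continue
        out.append(ProfileStation(s=float(s), area=sec.area, section=sec))

    n_missing = sum(st.missing for st in out)
    if n_missing > 0.5 * len(out):
        raise GeometryError(
            f"{n_missing}/{len(out)} profile stations missing — centerline "
            "or segmentation likely failed"
        )
    return out
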