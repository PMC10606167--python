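"""Parametric aortic-root + LV-outflow phantoms with analytic ground truth.

The phantom sweeps a polar radius profile r(s, φ) along a straight or
circular-arc axis: an LVOT tube, a smooth taper to the annulus, three
sinus-of-Valsalva bulges (one raised-cosine angular lobe per sinus, with a
compact axial bump), a sinotubular taper and a tubular ascending aorta,
closed with planar caps.  Nadirs sit on the annulus ring at the lobe-center
azimuths, the coronary ostia on the sinus wall at prescribed heights.

Because the surface is analytic, every one of the 22 pipeline measurements
has an independent ground truth, computed here by dense numerical
quadrature / contour scans — never by running the measurement pipeline.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import numpy as np
import trimesh
from scipy.optimize import brentq

from .centerline import Centerline
from .cross_section import Plane
from .errors import ValidationError
from .io import (
    CoronaryMeasurements,
    LandmarkSet,
    MeasurementReport,
    SectionMeasurements,
    SntjMeasurements,
    SovMeasurements,
)

__all__ = ["PhantomSpec", "PhantomTruth", "generate_phantom",
           "perturb_landmarks", "default_spec"]

_QUAD_POINTS = 10_000     # azimuthal quadrature for areas/centroids
_SCAN_STEP_DEG = 0.01     # dense chord scan for diameter truth


@dataclass
class PhantomSpec:
    """Geometry of one synthetic aortic root, all lengths in mm.

    The default values describe a TAVI-typical adult root: a 12.5 mm-radius
    annulus (area ≈ 491 mm²), 17 mm peak sinus radii 10 mm above the
    annulus, a 14 mm sinotubular junction, and coronary ostia 14 mm (left)
    and 12 mm (right) above the annulus plane.
    """

    r_lvot: float = 11.0
    r_annulus: float = 12.5
    sinus_peak_lcc: float = 17.0
    sinus_peak_rcc: float = 17.0
    sinus_peak_ncc: float = 17.0
    bulge_center_mm: float = 10.0    # height of the sinus belly above annulus
    bulge_width_mm: float = 5.0      # half-support of the axial bump
    r_stj: float = 14.0
    r_aorta: float = 14.0
    lv_length: float = 60.0
    annulus_to_stj: float = 22.0
    aorta_length: float = 30.0
    ostium_height_left: float = 14.0
    ostium_height_right: float = 12.0
    ostium_azimuth_left: float = 90.0    # deg; defaults sit on the lobe peaks
    ostium_azimuth_right: float = 210.0
    nadir_azimuth_lc: float = 90.0
    nadir_azimuth_rc: float = 210.0
    nadir_azimuth_nc: float = 330.0
    curvature_radius: float = float("inf")   # axis arc radius; inf = straight
    annulus_taper_mm: float = 6.0    # LVOT→annulus transition length
    stj_taper_mm: float = 5.0        # annulus→STJ transition length
    n_circ: int = 96
    axial_spacing: float = 1.0
    noise_mm: float = 0.0
    seed: int = 0

    def __post_init__(self):
        radii = [self.r_lvot, self.r_annulus, self.sinus_peak_lcc,
                 self.sinus_peak_rcc, self.sinus_peak_ncc, self.r_stj,
                 self.r_aorta]
        lengths = [self.lv_length, self.annulus_to_stj, self.aorta_length,
                   self.bulge_width_mm, self.axial_spacing]
        if min(radii) <= 0 or min(lengths) <= 0:
            raise ValidationError("all phantom radii and lengths must be > 0")
        if self.bulge_center_mm - self.bulge_width_mm < 0:
            raise ValidationError(
                "sinus bulge must not reach below the annulus "
                "(bulge_center_mm must be >= bulge_width_mm)")
        if max(self.ostium_height_left, self.ostium_height_right) \
                >= self.annulus_to_stj + self.aorta_length:
            raise ValidationError("ostium heights must lie on the root wall")
        if self.noise_mm >= 0.2 * min(radii):
            raise ValidationError("noise amplitude must be < 0.2·min radius")
        if not np.isinf(self.curvature_radius):
            if self.curvature_radius <= 2.0 * max(radii):
                raise ValidationError(
                    "curvature radius too small: the swept surface would "
                    "self-intersect")
            if self.total_length / self.curvature_radius >= np.pi:
                raise ValidationError("axis arc would exceed a half-turn")
        if self.n_circ < 16:
            raise ValidationError("n_circ must be at least 16")

    # -- axis ----------------------------------------------------------------

    @property
    def total_length(self) -> float:
        return self.lv_length + self.annulus_to_stj + self.aorta_length

    @property
    def s_annulus(self) -> float:
        return self.lv_length

    def axis_point(self, s):
        """Centerline point(s) at arc length s (vectorized)."""
        s = np.asarray(s, dtype=float)
        if np.isinf(self.curvature_radius):
            out = np.zeros(s.shape + (3,))
            out[..., 2] = s
            return out
        R = self.curvature_radius
        th = s / R
        return np.stack([R * (1 - np.cos(th)), np.zeros_like(th),
                         R * np.sin(th)], axis=-1)

    def axis_frame(self, s):
        """(tangent, u1, u2) orthonormal frame at arc length s (vectorized).

        u1 lies in the bending plane, u2 = +y; for a straight axis the frame
        is the world frame.  φ is measured from u1 toward u2.
        """
        s = np.asarray(s, dtype=float)
        if np.isinf(self.curvature_radius):
            shape = s.shape + (3,)
            t = np.zeros(shape); t[..., 2] = 1.0
            u1 = np.zeros(shape); u1[..., 0] = 1.0
            u2 = np.zeros(shape); u2[..., 1] = 1.0
            return t, u1, u2
        th = s / self.curvature_radius
        zeros = np.zeros_like(th)
        t = np.stack([np.sin(th), zeros, np.cos(th)], axis=-1)
        u1 = np.stack([np.cos(th), zeros, -np.sin(th)], axis=-1)
        u2 = np.zeros_like(t); u2[..., 1] = 1.0
        return t, u1, u2

    # -- radius field ---------------------------------------------------------

    def base_radius(self, s):
        """Axisymmetric base profile r_lvot → r_annulus → r_stj → r_aorta."""
        s = np.asarray(s, dtype=float)
        s_ann = self.s_annulus
        s_stj = s_ann + self.annulus_to_stj
        r = np.full_like(s, self.r_lvot, dtype=float)
        r = r + (self.r_annulus - self.r_lvot) * _smoothstep(
            s, s_ann - self.annulus_taper_mm, s_ann)
        r = r + (self.r_stj - self.r_annulus) * _smoothstep(
            s, s_ann, s_ann + self.stj_taper_mm)
        r = r + (self.r_aorta - self.r_stj) * _smoothstep(
            s, s_stj, s_stj + self.stj_taper_mm)
        return r

    def _lobes(self, phi):
        """Raised-cosine angular lobes (120° support each), one per sinus,
        centered on the nadir azimuths; returns an (..., 3) stack ordered
        lcc, rcc, ncc."""
        phi = np.asarray(phi, dtype=float)
        out = []
        for az in (self.nadir_azimuth_lc, self.nadir_azimuth_rc,
                   self.nadir_azimuth_nc):
            d = np.deg2rad((np.rad2deg(phi) - az + 180.0) % 360.0 - 180.0)
            lobe = np.where(np.abs(d) < np.pi / 3.0,
                            np.cos(1.5 * d) ** 2, 0.0)
            out.append(lobe)
        return np.stack(out, axis=-1)

    def _axial_bump(self, s):
        """Compact truncated-Gaussian axial bump, 1 at the bulge belly and
        exactly 0 beyond ± bulge_width_mm, so the aorta radius is exactly
        constant above the sinuses (gives the SNTJ plateau its truth)."""
        s = np.asarray(s, dtype=float)
        u = (s - self.s_annulus - self.bulge_center_mm) / self.bulge_width_mm
        raw = np.exp(-4.5 * u ** 2) - np.exp(-4.5)
        return np.where(np.abs(u) < 1.0, raw / (1.0 - np.exp(-4.5)), 0.0)

    def bulge_amplitudes(self) -> np.ndarray:
        base_at_center = float(self.base_radius(
            self.s_annulus + self.bulge_center_mm))
        amps = np.array([self.sinus_peak_lcc, self.sinus_peak_rcc,
                         self.sinus_peak_ncc]) - base_at_center
        if np.any(amps < 0):
            raise ValidationError(
                "sinus peak radii must exceed the base radius at the bulge "
                f"center ({base_at_center:.2f} mm)")
        return amps

    def radius(self, s, phi):
        """Full radius field r(s, φ); s and phi broadcast together."""
        s = np.asarray(s, dtype=float)
        phi = np.asarray(phi, dtype=float)
        lobes = self._lobes(phi)
        bump = self._axial_bump(s)
        return (self.base_radius(s)
                + (lobes @ self.bulge_amplitudes()) * bump)

    def surface_point(self, s, phi):
        """World point(s) on the surface at (s, φ)."""
        s = np.asarray(s, dtype=float)
        phi = np.asarray(phi, dtype=float)
        s, phi = np.broadcast_arrays(s, phi)
        _, u1, u2 = self.axis_frame(s)
        r = self.radius(s, phi)[..., None]
        return (self.axis_point(s)
                + r * (np.cos(phi)[..., None] * u1
                       + np.sin(phi)[..., None] * u2))

    @property
    def plateau_height(self) -> float:
        """Height above the annulus beyond which r(s, φ) is constant in s."""
        transitions = [self.bulge_center_mm + self.bulge_width_mm,
                       self.stj_taper_mm]
        if abs(self.r_aorta - self.r_stj) > 0:
            transitions.append(self.annulus_to_stj + self.stj_taper_mm)
        return max(transitions)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown phantom spec keys: {sorted(unknown)}")
        return cls(**d)


def _smoothstep(s, lo, hi):
    t = np.clip((np.asarray(s, dtype=float) - lo) / (hi - lo), 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def default_spec(**overrides) -> PhantomSpec:
    """The default TAVI-like phantom, optionally with field overrides."""
    return replace(PhantomSpec(), **overrides)


# --------------------------------------------------------------------------
# truth computation (dense quadrature / contour scans; pipeline-free)
# --------------------------------------------------------------------------

def _ring_contour(spec: PhantomSpec, s: float, n: int) -> np.ndarray:
    """Dense 2D polygon of the transverse section at station s, in the
    (u1, u2) frame of that station (the section of the swept surface by the
    normal plane at s is exactly the ring r(s, φ))."""
    phi = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    r = spec.radius(np.full(n, s), phi)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi)])


def _poly_area(c: np.ndarray) -> float:
    x, y = c[:, 0], c[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _poly_perimeter(c: np.ndarray) -> float:
    return float(np.sum(np.linalg.norm(np.diff(
        np.vstack([c, c[:1]]), axis=0), axis=1)))


def _poly_centroid(c: np.ndarray) -> np.ndarray:
    x, y = c[:, 0], c[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * np.sum(cross)
    return np.array([np.sum((x + xn) * cross), np.sum((y + yn) * cross)]) / (6 * a)


def _chord_crossings(c: np.ndarray, point: np.ndarray, d: np.ndarray
                     ) -> np.ndarray:
    """All signed crossing parameters of line point + t·d with polygon c."""
    p0, p1 = c, np.roll(c, -1, axis=0)
    edge = p1 - p0
    rel = p0 - point
    denom = d[0] * edge[:, 1] - d[1] * edge[:, 0]
    ok = np.abs(denom) > 1e-14
    t = (rel[:, 0] * edge[:, 1] - rel[:, 1] * edge[:, 0])[ok] / denom[ok]
    u = (rel[:, 0] * d[1] - rel[:, 1] * d[0])[ok] / denom[ok]
    return t[(u >= 0.0) & (u < 1.0)]


def _dense_min_max(c: np.ndarray, step_deg: float = _SCAN_STEP_DEG,
                   max_edges: int = 3600) -> tuple[float, float]:
    """Brute-force centroid-chord scan at ``step_deg`` over the polygon,
    vectorized over direction chunks."""
    if len(c) > max_edges:  # polygonization error at 3600 edges is ~5e-7 rel.
        c = c[:: len(c) // max_edges]
    centroid = _poly_centroid(c)
    p0, p1 = c, np.roll(c, -1, axis=0)
    edge = p1 - p0                       # (M, 2)
    rel = p0 - centroid                  # (M, 2)
    cross_rel_edge = rel[:, 0] * edge[:, 1] - rel[:, 1] * edge[:, 0]
    thetas = np.deg2rad(np.arange(0.0, 180.0, step_deg))
    best_min, best_max = np.inf, -np.inf
    for start in range(0, len(thetas), 512):
        th = thetas[start:start + 512]
        d = np.column_stack([np.cos(th), np.sin(th)])        # (K, 2)
        denom = d[:, :1] * edge[:, 1] - d[:, 1:] * edge[:, 0]  # (K, M)
        ok = np.abs(denom) > 1e-14
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(ok, cross_rel_edge / denom, np.nan)
            u = np.where(ok, (rel[:, 0] * d[:, 1:] - rel[:, 1] * d[:, :1])
                         / denom, np.nan)
        hit = (u >= 0.0) & (u < 1.0)
        t = np.where(hit, t, np.nan)
        # a direction may lose a crossing to an exact-vertex hit; such rows
        # are all-NaN and get skipped, like any non-star-shaped direction
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            t_pos = np.nanmax(np.where(t > 0, t, np.nan), axis=1)
            t_neg = np.nanmin(np.where(t < 0, t, np.nan), axis=1)
        chords = t_pos - t_neg
        valid = np.isfinite(chords)
        if valid.any():
            best_min = min(best_min, float(np.min(chords[valid])))
            best_max = max(best_max, float(np.max(chords[valid])))
    return float(best_min), float(best_max)


def _section_truth(c: np.ndarray, scan_step_deg: float) -> SectionMeasurements:
    area = abs(_poly_area(c))
    perim = _poly_perimeter(c)
    d_min, d_max = _dense_min_max(c, scan_step_deg)
    return SectionMeasurements(
        area=area, perimeter=perim,
        diameter_min=d_min, diameter_max=d_max,
        diameter_avg=0.5 * (d_min + d_max),
        diameter_area_derived=2.0 * np.sqrt(area / np.pi),
        diameter_perimeter_derived=perim / np.pi,
    )


def _oblique_section_contour(spec: PhantomSpec, plane: Plane,
                             s_guess: float, n: int) -> np.ndarray:
    """Dense contour of the surface cut by an arbitrary (near-transverse)
    plane, by root-finding the plane crossing of each meridian s ↦ P(s, φ);
    returned in the plane's own 2D frame."""
    phi = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    lo = max(s_guess - 12.0, 0.0)
    hi = min(s_guess + 12.0, spec.total_length)
    pts = []
    for p in phi:
        def f(s, p=p):
            return float(np.dot(spec.surface_point(s, p) - plane.origin,
                                plane.normal))
        try:
            s_root = brentq(f, lo, hi, xtol=1e-10)
        except ValueError as e:
            raise ValidationError(
                "oblique truth section: plane does not cross the meridian "
                f"at φ={np.rad2deg(p):.1f}°") from e
        pts.append(spec.surface_point(s_root, p))
    return plane.to_plane_coords(np.asarray(pts))


@dataclass
class PhantomTruth:
    """Analytic ground truth for one phantom.

    ``report`` holds the 22 measurement truths in the same container the
    pipeline emits.  Stations are stored as heights above the annulus so
    they can be compared across differently parameterized centerlines.
    """

    report: MeasurementReport
    landmarks: LandmarkSet
    centerline: Centerline
    annulus_plane: Plane
    sov_height_mm: float
    sntj_height_mm: float
    area_profile: np.ndarray        # (n, 2): height above annulus, area
    spec: PhantomSpec = field(repr=False, default=None)


def _compute_truth(spec: PhantomSpec, landmarks: LandmarkSet,
                   quad_n: int = _QUAD_POINTS,
                   scan_step_deg: float = _SCAN_STEP_DEG) -> PhantomTruth:
    s_ann = spec.s_annulus
    t_ann, _, _ = spec.axis_frame(s_ann)
    ann_plane = Plane(origin=landmarks.nadir_centroid(), normal=t_ann)

    # annulus: the nadir plane is the normal plane at s_ann, whose section
    # is exactly the annulus ring (a circle of radius r_annulus)
    ann_contour = _ring_contour(spec, s_ann, quad_n)
    ann_truth = _section_truth(ann_contour, scan_step_deg)

    # LVOT: annulus plane translated 4 mm down the true axis, same normal;
    # for a curved axis this plane is oblique to the local frame
    s_lvot = s_ann - 4.0
    lvot_plane = Plane(origin=spec.axis_point(s_lvot), normal=t_ann)
    if np.isinf(spec.curvature_radius):
        lvot_contour = _ring_contour(spec, s_lvot, quad_n)
    else:
        lvot_contour = _oblique_section_contour(spec, lvot_plane, s_lvot,
                                                quad_n)
    lvot_truth = _section_truth(lvot_contour, scan_step_deg)

    # area profile over the root at the pipeline's 1 mm spacing
    heights = np.arange(0.0, min(40.0, spec.annulus_to_stj
                                 + spec.aorta_length - 2.0) + 0.5, 1.0)
    areas = np.array([abs(_poly_area(_ring_contour(spec, s_ann + h, quad_n)))
                      for h in heights])
    h_sov = float(heights[int(np.argmax(areas))])
    h_sntj = float(spec.plateau_height)

    s_sov = s_ann + h_sov
    sov_contour = _ring_contour(spec, s_sov, quad_n)
    sov_centroid = _poly_centroid(sov_contour)
    _, u1_sov, u2_sov = spec.axis_frame(s_sov)
    axis_sov = spec.axis_point(s_sov)
    sinus = {}
    for key, nadir in (("lcc", landmarks.nadir_left),
                       ("rcc", landmarks.nadir_right),
                       ("ncc", landmarks.nadir_noncoronary)):
        # orthogonal projection of the nadir onto the SOV plane, expressed
        # in the (u1, u2) frame the ring contour lives in
        rel = nadir - axis_sov
        p2 = np.array([np.dot(rel, u1_sov), np.dot(rel, u2_sov)])
        d = p2 - sov_centroid
        d = d / np.linalg.norm(d)
        ts = _chord_crossings(sov_contour, sov_centroid, d)
        sinus[key] = float(ts[ts > 0].max() - ts[ts < 0].min())

    sntj_contour = _ring_contour(spec, s_ann + h_sntj, quad_n)
    sntj_min, sntj_max = _dense_min_max(sntj_contour, scan_step_deg)

    lch = float(np.dot(landmarks.left_coronary_ostium - ann_plane.origin,
                       ann_plane.normal))
    rch = float(np.dot(landmarks.right_coronary_ostium - ann_plane.origin,
                       ann_plane.normal))

    report = MeasurementReport(
        annulus=ann_truth,
        lvot=lvot_truth,
        sntj=SntjMeasurements(diameter_min=sntj_min, diameter_max=sntj_max,
                              diameter_avg=0.5 * (sntj_min + sntj_max)),
        sov=SovMeasurements(diameter_lcc=sinus["lcc"],
                            diameter_rcc=sinus["rcc"],
                            diameter_ncc=sinus["ncc"]),
        coronary=CoronaryMeasurements(height_left=lch, height_right=rch),
        metadata={"truth": True, "spec": spec.to_dict()},
    )
    report.validate()

    s_axis = np.arange(0.0, spec.total_length + 0.25, 0.5)
    true_cl = Centerline(points=spec.axis_point(s_axis))
    return PhantomTruth(
        report=report, landmarks=landmarks, centerline=true_cl,
        annulus_plane=ann_plane, sov_height_mm=h_sov, sntj_height_mm=h_sntj,
        area_profile=np.column_stack([heights, areas]), spec=spec,
    )


# --------------------------------------------------------------------------
# mesh generation
# --------------------------------------------------------------------------

def _build_landmarks(spec: PhantomSpec) -> LandmarkSet:
    s_ann = spec.s_annulus

    def ring_point(s, az_deg, radius=None):
        phi = np.deg2rad(az_deg)
        r = radius if radius is not None else float(spec.radius(s, phi))
        _, u1, u2 = spec.axis_frame(s)
        return spec.axis_point(s) + r * (np.cos(phi) * u1 + np.sin(phi) * u2)

    return LandmarkSet(
        nadir_left=ring_point(s_ann, spec.nadir_azimuth_lc, spec.r_annulus),
        nadir_right=ring_point(s_ann, spec.nadir_azimuth_rc, spec.r_annulus),
        nadir_noncoronary=ring_point(s_ann, spec.nadir_azimuth_nc,
                                     spec.r_annulus),
        left_coronary_ostium=ring_point(s_ann + spec.ostium_height_left,
                                        spec.ostium_azimuth_left),
        right_coronary_ostium=ring_point(s_ann + spec.ostium_height_right,
                                         spec.ostium_azimuth_right),
    )


def generate_phantom(spec: PhantomSpec | None = None
                     ) -> tuple[trimesh.Trimesh, LandmarkSet, PhantomTruth]:
    """Build the phantom mesh, its landmark set and its analytic truth.

    The mesh is a closed 2-manifold: rings of ``n_circ`` vertices every
    ``axial_spacing`` mm, quad strips split into triangles, planar end caps
    fanned to the axis points.  Radial surface noise (uniform in
    ±noise_mm, seeded) perturbs wall vertices only; the truth is computed
    from the noise-free analytic surface.  Deterministic for a fixed seed.
    """
    spec = spec or PhantomSpec()
    landmarks = _build_landmarks(spec)
    truth = _compute_truth(spec, landmarks)

    n_ax = int(round(spec.total_length / spec.axial_spacing)) + 1
    s_vals = np.linspace(0.0, spec.total_length, n_ax)
    phi = np.linspace(0.0, 2 * np.pi, spec.n_circ, endpoint=False)

    ss, pp = np.meshgrid(s_vals, phi, indexing="ij")
    pts = spec.surface_point(ss, pp)          # (n_ax, n_circ, 3)

    if spec.noise_mm > 0:
        rng = np.random.default_rng(spec.seed)
        noise = spec.noise_mm * rng.uniform(-1.0, 1.0, size=ss.shape)
        _, u1, u2 = spec.axis_frame(ss)
        radial = np.cos(pp)[..., None] * u1 + np.sin(pp)[..., None] * u2
        pts = pts + noise[..., None] * radial

    nc = spec.n_circ
    verts = pts.reshape(-1, 3)
    faces = []
    for i in range(n_ax - 1):
        a = i * nc + np.arange(nc)
        b = i * nc + (np.arange(nc) + 1) % nc
        c = a + nc
        d = b + nc
        faces.append(np.column_stack([a, b, d]))
        faces.append(np.column_stack([a, d, c]))
    # end caps: fans to the axis points
    bottom_center = len(verts)
    top_center = len(verts) + 1
    verts = np.vstack([verts, spec.axis_point(0.0),
                       spec.axis_point(spec.total_length)])
    ring0 = np.arange(nc)
    ringN = (n_ax - 1) * nc + np.arange(nc)
    faces.append(np.column_stack([ring0, np.full(nc, bottom_center),
                                  (ring0 + 1) % nc]))
    faces.append(np.column_stack([ringN, (ringN - (n_ax - 1) * nc + 1) % nc
                                  + (n_ax - 1) * nc, np.full(nc, top_center)]))
    mesh = trimesh.Trimesh(vertices=verts, faces=np.vstack(faces),
                           process=False)
    return mesh, landmarks, truth


def perturb_landmarks(lm: LandmarkSet, sigma: float,
                      seed: int | np.random.Generator = 0) -> LandmarkSet:
    """Isotropic Gaussian jitter of all five landmarks.

    With σ > 0 each landmark moves by a 3D normal displacement; the
    displacement magnitude follows a χ₃ distribution with mean σ·√(8/π).
    Used for nadir-sensitivity studies of the plane-derived measurements.
    """
    if sigma < 0:
        raise ValidationError("sigma must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    if sigma == 0:
        return lm
    from .io import LANDMARK_NAMES
    return LandmarkSet(**{
        name: getattr(lm, name) + rng.normal(0.0, sigma, size=3)
        for name in LANDMARK_NAMES
    })
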