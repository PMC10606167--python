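"""Lumen centerline extraction.

The measurement planes all slide along an arc-length-parameterized axis
through the LV outflow and aortic root.  The primary extractor contracts
the surface onto its medial curve by iterated Laplacian smoothing with
per-vertex attraction anchors (Laplacian-based contraction), then reduces
the contracted graph to its longest geodesic path, smooths and resamples
it.  A plane-marching extractor (repeated cross-section centroid tracking)
is provided as an independent, cheaper alternative and cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph
import scipy.sparse.linalg as spla
from scipy.interpolate import splev, splprep
import trimesh

from .cross_section import (
    DegenerateSectionError,
    EmptySectionError,
    Plane,
    slice_mesh,
)
from .errors import ConvergenceError, TopologyError, ValidationError

__all__ = [
    "Centerline",
    "LBCParams",
    "extract_centerline_lbc",
    "extract_centerline_marching",
    "resample_centerline",
    "tangent_at",
    "orient_centerline",
]


@dataclass
class Centerline:
    """Ordered polyline through the lumen, parameterized by arc length (mm).

    ``arclength[0]`` is 0 at the LV end once the line has been oriented
    (see :func:`orient_centerline`); before orientation the direction is
    arbitrary.
    """

    points: np.ndarray
    arclength: np.ndarray = field(init=False)

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
            raise ValidationError("centerline needs at least 2 points in 3D")
        # drop exactly duplicated consecutive points
        keep = np.r_[True, np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-12]
        pts = pts[keep]
        if len(pts) < 2:
            raise ValidationError("centerline degenerates to a single point")
        self.points = pts
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        self.arclength = np.r_[0.0, np.cumsum(seg)]

    @property
    def length(self) -> float:
        return float(self.arclength[-1])

    def _check_s(self, s: float) -> float:
        if not (-1e-9 <= s <= self.length + 1e-9):
            raise ValidationError(
                f"arc length {s} outside [0, {self.length:.3f}]")
        return float(np.clip(s, 0.0, self.length))

    def point_at(self, s: float) -> np.ndarray:
        s = self._check_s(s)
        return np.array([np.interp(s, self.arclength, self.points[:, i])
                         for i in range(3)])

    def tangent_at(self, s: float, half_window: float = 2.0) -> np.ndarray:
        """Unit tangent by a symmetric finite difference over ±half_window
        mm of arc length (clamped at the ends).

        The window averages out the sub-millimetre wobble a skeletonized
        polyline carries; a single-segment difference would pass that
        wobble straight into the orientation of every sliding plane.
        """
        s = self._check_s(s)
        h = min(half_window, self.length / 2.0)
        s0 = max(s - h, 0.0)
        s1 = min(s + h, self.length)
        t = self.point_at(s1) - self.point_at(s0)
        norm = np.linalg.norm(t)
        if norm < 1e-12:
            raise ValidationError("degenerate tangent: zero chord")
        return t / norm

    def reversed(self) -> "Centerline":
        return Centerline(points=self.points[::-1].copy())

    def closest_s(self, point: np.ndarray) -> float:
        """Arc length of the point on the polyline nearest to ``point``
        (exact orthogonal projection onto the segments)."""
        p = np.asarray(point, dtype=float)
        a = self.points[:-1]
        seg = self.points[1:] - a
        seg_len2 = np.einsum("ij,ij->i", seg, seg)
        t = np.clip(np.einsum("ij,ij->i", p - a, seg)
                    / np.maximum(seg_len2, 1e-24), 0.0, 1.0)
        proj = a + t[:, None] * seg
        d2 = np.einsum("ij,ij->i", proj - p, proj - p)
        i = int(np.argmin(d2))
        return float(self.arclength[i] + t[i] * np.sqrt(seg_len2[i]))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray
                    ) -> "Centerline":
        return Centerline(points=self.points @ rotation.T + translation)


def resample_centerline(cl: Centerline, spacing: float) -> Centerline:
    """Resample at (near-)uniform arc-length spacing, keeping both endpoints.

    The actual spacing is ``length / round(length / spacing)`` so the
    endpoints are preserved exactly; total length is preserved to within one
    spacing (chords only ever shorten a curve).
    """
    if spacing <= 0:
        raise ValidationError("spacing must be positive")
    if cl.length < spacing:
        raise ValidationError(
            f"centerline length {cl.length:.3f} mm shorter than spacing")
    n_seg = max(1, int(round(cl.length / spacing)))
    s_new = np.linspace(0.0, cl.length, n_seg + 1)
    pts = np.column_stack([np.interp(s_new, cl.arclength, cl.points[:, i])
                           for i in range(3)])
    return Centerline(points=pts)


def tangent_at(cl: Centerline, s: float) -> np.ndarray:
    """Unit tangent of the centerline at arc length ``s``."""
    return cl.tangent_at(s)


def orient_centerline(cl: Centerline, annulus_centroid: np.ndarray
                      ) -> tuple[Centerline, float]:
    """Fix the direction convention: arc length 0 at the LV end.

    The LV end is the endpoint farther, along the path, from the annulus
    centroid (the nadir centroid): the LV cavity extends well below the
    annulus while the ascending-aorta segment above it is shorter.  Returns
    the oriented centerline and the annulus station s on it.
    """
    s_ann = cl.closest_s(annulus_centroid)
    if s_ann < cl.length - s_ann:
        cl = cl.reversed()
        s_ann = cl.length - s_ann
    return cl, s_ann


# --------------------------------------------------------------------------
# Laplacian-based contraction
# --------------------------------------------------------------------------

@dataclass
class LBCParams:
    """Contraction parameters (exposed; the defaults follow the published
    regime of the contraction method).

    initial_weight_ratio
        Laplacian:attraction weight ratio at iteration 0, applied after the
        Laplacian is scaled to unit mean diagonal (so the ratio is
        dimensionless).
    contraction_scale
        Factor applied to the Laplacian weight each iteration.
    tol_mm
        Stop when the mean vertex displacement of an iteration falls below
        this, once contraction has actually begun.
    area_stop
        Also stop when the mesh surface area has collapsed below this
        fraction of the original — the signature of a fully contracted
        skeleton.
    """

    target_density: float = 1.0      # surface samples per mm²
    initial_weight_ratio: float = 64.0
    contraction_scale: float = 2.0
    tol_mm: float = 0.01
    max_iter: int = 20
    area_stop: float = 0.005
    max_attraction: float = 1e6      # cap on per-vertex anchor weight
    smooth_window_mm: float = 8.0    # arc-length median window for the path
    spline_smoothing: float = 0.3    # per-point RMS budget (mm) of the spline
    recenter_passes: int = 2         # centroidal refinement iterations
    resample_mm: float = 0.5


def _cotangent_laplacian(vertices: np.ndarray, faces: np.ndarray) -> sp.csr_matrix:
    """Cotangent-weight Laplacian L = D − W; degenerate-triangle cotangents
    are clamped so the contracted (near-flat) mesh stays solvable."""
    v = vertices[faces]  # (F, 3, 3)
    ii, jj, ww = [], [], []
    for corner in range(3):
        a = v[:, corner]
        b = v[:, (corner + 1) % 3]
        c = v[:, (corner + 2) % 3]
        e1 = b - a
        e2 = c - a
        cross = np.linalg.norm(np.cross(e1, e2), axis=1)
        cot = np.einsum("ij,ij->i", e1, e2) / np.maximum(cross, 1e-12)
        cot = np.clip(np.nan_to_num(cot), -1e5, 1e5)
        i = faces[:, (corner + 1) % 3]
        j = faces[:, (corner + 2) % 3]
        ii.extend([i, j])
        jj.extend([j, i])
        ww.extend([0.5 * cot, 0.5 * cot])
    n = len(vertices)
    W = sp.csr_matrix((np.concatenate(ww),
                       (np.concatenate(ii), np.concatenate(jj))), shape=(n, n))
    D = sp.diags(np.asarray(W.sum(axis=1)).ravel())
    return (D - W).tocsr()


def _one_ring_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    fv = vertices[faces]
    fa = 0.5 * np.linalg.norm(
        np.cross(fv[:, 1] - fv[:, 0], fv[:, 2] - fv[:, 0]), axis=1)
    areas = np.zeros(len(vertices))
    for corner in range(3):
        np.add.at(areas, faces[:, corner], fa / 3.0)
    return areas


def _ensure_density(mesh: trimesh.Trimesh, target: float) -> trimesh.Trimesh:
    """Subdivide until the vertex density reaches ``target`` points/mm²."""
    m = mesh
    for _ in range(4):
        if len(m.vertices) / m.area >= target:
            break
        m = trimesh.Trimesh(*trimesh.remesh.subdivide(m.vertices, m.faces),
                            process=False)
    return m


def _contract(mesh: trimesh.Trimesh, params: LBCParams) -> np.ndarray:
    """Run the contraction iterations; returns contracted vertex positions."""
    V0 = np.asarray(mesh.vertices, dtype=float)
    F = np.asarray(mesh.faces, dtype=int)
    V = V0.copy()
    ring0 = _one_ring_areas(V0, F)
    area0 = float(ring0.sum())
    n = len(V)

    L = _cotangent_laplacian(V, F)
    mean_diag = float(np.mean(np.abs(L.diagonal()))) or 1.0
    w_l = params.initial_weight_ratio / mean_diag
    w_h = np.ones(n)

    started = False
    disp = np.inf
    area_ratio = 1.0
    for _ in range(params.max_iter):
        A_up = (w_l * L)
        # least squares [w_l L; diag(w_h)] x ≈ [0; w_h v] via normal equations
        lhs = (A_up.T @ A_up + sp.diags(w_h ** 2)).tocsc()
        rhs = (w_h ** 2)[:, None] * V
        solve = spla.factorized(lhs)
        V_new = np.column_stack([solve(rhs[:, k]) for k in range(3)])
        disp = float(np.mean(np.linalg.norm(V_new - V, axis=1)))
        V = V_new
        ring = np.maximum(_one_ring_areas(V, F), 1e-12)
        area_ratio = float(ring.sum()) / area0
        if area_ratio < params.area_stop:
            break
        if disp > 10 * params.tol_mm:
            started = True
        elif started and disp < params.tol_mm:
            break
        # re-weight: contraction grows, anchors stiffen where rings collapse
        w_l *= params.contraction_scale
        w_h = np.minimum(np.sqrt(ring0 / ring), params.max_attraction)
        L = _cotangent_laplacian(V, F)
    else:
        if area_ratio > 0.2:
            raise ConvergenceError(
                "Laplacian contraction did not converge (surface area only "
                f"reduced to {area_ratio:.2f} of the original after "
                f"{params.max_iter} iterations)",
                iterations=params.max_iter, residual=disp)
    return V


def _longest_geodesic_path(positions: np.ndarray, edges: np.ndarray
                           ) -> np.ndarray:
    """Double-sweep farthest-point search for the longest geodesic path in
    the contracted vertex graph; returns the ordered path positions."""
    n = len(positions)
    w = np.linalg.norm(positions[edges[:, 0]] - positions[edges[:, 1]], axis=1)
    w = w + 1e-9  # contracted edges may have zero length
    g = sp.csr_matrix((np.r_[w, w],
                       (np.r_[edges[:, 0], edges[:, 1]],
                        np.r_[edges[:, 1], edges[:, 0]])), shape=(n, n))
    d0 = csgraph.dijkstra(g, indices=0)
    if np.isinf(d0).any():
        # multiple components: skeletonize the largest one
        comp_n, labels = csgraph.connected_components(g, directed=False)
        main = np.bincount(labels).argmax()
        if comp_n > 1:
            keep = np.flatnonzero(labels == main)
            remap = -np.ones(n, dtype=int)
            remap[keep] = np.arange(len(keep))
            mask = (labels[edges[:, 0]] == main) & (labels[edges[:, 1]] == main)
            return _longest_geodesic_path(positions[keep], remap[edges[mask]])
        raise TopologyError("contracted graph is disconnected")
    u = int(np.argmax(d0))
    du, pred = csgraph.dijkstra(g, indices=u, return_predecessors=True)
    v = int(np.argmax(du))
    path = [v]
    while path[-1] != u:
        p = int(pred[path[-1]])
        if p < 0:
            raise TopologyError("no path between skeleton endpoints")
        path.append(p)
    return positions[np.array(path[::-1])]


def _smooth_path(path: np.ndarray, params: LBCParams) -> np.ndarray:
    """Arc-length windowed-median smoothing followed by a cubic smoothing
    spline; the sliding planes need a differentiable axis, not the raw
    contracted zigzag.  The median kills the occasional under-contracted
    outlier vertex; windows that fall inside a long skeleton-edge jump are
    empty and simply skipped (the spline bridges them)."""
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    s = np.r_[0.0, np.cumsum(seg)]
    total = s[-1]
    if total < 1e-6:
        raise TopologyError("skeleton path has zero length")
    step = max(params.smooth_window_mm / 4.0, 0.25)
    centers = np.arange(0.0, total + 0.5 * step, step)
    half = params.smooth_window_mm / 2.0
    smoothed = []
    for c in centers:
        m = (s >= c - half) & (s <= c + half)
        if m.any():
            smoothed.append(np.median(path[m], axis=0))
    smoothed = np.asarray(smoothed)
    keep = np.r_[True, np.linalg.norm(np.diff(smoothed, axis=0), axis=1) > 1e-9]
    smoothed = smoothed[keep]
    if len(smoothed) >= 4:
        tck, _ = splprep(smoothed.T,
                         s=len(smoothed) * params.spline_smoothing ** 2, k=3)
        u = np.linspace(0, 1, max(int(total / params.resample_mm) + 1, 16))
        smoothed = np.column_stack(splev(u, tck))
    return smoothed


def _recenter_on_sections(mesh: trimesh.Trimesh, cl: Centerline,
                          spacing: float = 2.0) -> Centerline:
    """Embedding refinement: move each interior node to the centroid of the
    mesh cross-section perpendicular to the local tangent.

    Curve contraction systematically shortens a bent axis toward its chord;
    one centroidal re-centering pass removes that bias.  Nodes whose plane
    fails to cut a usable section (near the end caps) keep their position.
    """
    nodes = resample_centerline(cl, spacing)
    out = nodes.points.copy()
    for i, s in enumerate(nodes.arclength):
        plane = Plane(origin=nodes.points[i], normal=nodes.tangent_at(s))
        try:
            sec = slice_mesh(mesh, plane, anchor=nodes.points[i])
        except (EmptySectionError, DegenerateSectionError):
            continue
        if np.linalg.norm(sec.centroid - nodes.points[i]) < 2.0 * spacing:
            out[i] = sec.centroid
    return Centerline(points=out)


def extract_centerline_lbc(mesh: trimesh.Trimesh,
                           params: LBCParams | None = None) -> Centerline:
    """Extract the lumen centerline by Laplacian-based contraction.

    The surface is (if needed) subdivided to the target sample density,
    contracted onto its medial curve, reduced to the longest geodesic path
    of the contracted vertex graph (side branches are discarded — the
    anatomy of interest is a single lumen axis), smoothed, re-centered on
    cross-section centroids, and resampled at sub-millimetre spacing.
    Deterministic for fixed input and parameters.
    """
    params = params or LBCParams()
    dense = _ensure_density(mesh, params.target_density)
    contracted = _contract(dense, params)
    path = _longest_geodesic_path(contracted, np.asarray(dense.edges_unique))
    smoothed = _smooth_path(path, params)
    for _ in range(params.recenter_passes):
        refined = _recenter_on_sections(mesh, Centerline(points=smoothed))
        smoothed = _smooth_path(refined.points, params)
    return resample_centerline(Centerline(points=smoothed), params.resample_mm)


# --------------------------------------------------------------------------
# plane-marching extraction
# --------------------------------------------------------------------------

def extract_centerline_marching(mesh: trimesh.Trimesh, seed_plane: Plane,
                                step: float = 1.0,
                                max_steps: int = 2000) -> Centerline:
    """Centerline by iterative cross-section centroid tracking.

    From the seed section's centroid the plane is stepped along the current
    direction, re-centered on the new section's centroid, and the direction
    updated to follow the centroid track; both directions from the seed are
    explored.  The march ends cleanly when the plane exits the mesh or the
    centroid jumps abruptly (the plane has reached an end cap); sustained
    growth of the step displacement raises a divergence error.
    """
    if step <= 0:
        raise ValidationError("step must be positive")
    seed_sec = slice_mesh(mesh, seed_plane, anchor=seed_plane.origin)
    c0 = seed_sec.centroid

    halves = []
    for sign in (1.0, -1.0):
        pts = [c0]
        direction = sign * seed_plane.normal
        growing = 0
        last_jump = 0.0
        while len(pts) < max_steps:
            origin = pts[-1] + step * direction
            try:
                sec = slice_mesh(mesh, Plane(origin=origin, normal=direction),
                                 anchor=origin)
            except (EmptySectionError, DegenerateSectionError):
                break  # plane exited the mesh: this direction is done
            c_new = sec.centroid
            jump = float(np.linalg.norm(c_new - pts[-1]))
            if jump > 2.5 * step:
                break  # centroid snapped away: cap or branch point reached
            growing = growing + 1 if jump > last_jump + 1e-9 else 0
            if growing >= 4 and jump > 1.5 * step:
                raise ConvergenceError(
                    "marching diverged: step displacement grew for "
                    f"{growing} consecutive steps (last {jump:.2f} mm)",
                    iterations=len(pts), residual=jump)
            last_jump = jump
            if jump < 1e-9:
                break
            direction = (c_new - pts[-1]) / jump
            pts.append(c_new)
        else:
            raise ConvergenceError(
                f"marching exceeded {max_steps} steps without exiting the "
                "mesh", iterations=max_steps)
        halves.append(pts)

    points = np.asarray(halves[1][::-1] + halves[0][1:])
    return Centerline(points=points)
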