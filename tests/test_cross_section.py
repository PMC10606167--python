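"""Plane-mesh sections and per-section metrics against closed forms and
independent 2D computational-geometry oracles."""

import numpy as np
import pytest
import trimesh
from shapely.geometry import Polygon

from conftest import apply_rigid, random_rigid
from tavimetrics.centerline import Centerline
from tavimetrics.cross_section import (
    CrossSection,
    Plane,
    area_profile,
    derived_diameters,
    min_max_diameters,
    polygon_area,
    polygon_centroid,
    polygon_perimeter,
    slice_mesh,
)
from tavimetrics.errors import (
    EmptySectionError,
    GeometryError,
    ValidationError,
)

R10_AREA = np.pi * 100.0
R10_PERIM = 2 * np.pi * 10.0


def _fine_cylinder(sections=512):
    return trimesh.creation.cylinder(radius=10.0, height=80.0,
                                     sections=sections)


class TestSliceMesh:
    def test_cylinder_transverse_closed_forms(self):
        mesh = _fine_cylinder()
        sec = slice_mesh(mesh, Plane(origin=[0, 0, 0], normal=[0, 0, 1]),
                         anchor=[0, 0, 0])
        assert abs(sec.area - R10_AREA) / R10_AREA < 0.005
        assert abs(sec.perimeter - R10_PERIM) / R10_PERIM < 0.005
        assert np.linalg.norm(sec.centroid) < 1e-6

    def test_oblique_60deg_cut(self):
        mesh = _fine_cylinder()
        a = np.deg2rad(60.0)
        sec = slice_mesh(mesh,
                         Plane(origin=[0, 0, 0],
                               normal=[np.sin(a), 0, np.cos(a)]),
                         anchor=[0, 0, 0])
        expected = R10_AREA / np.cos(a)
        assert abs(sec.area - expected) / expected < 0.005

    def test_two_lobed_anchor_selection(self):
        """A plane cutting two parallel tubes returns only the loop holding
        the anchor, verified by an independent point-in-polygon oracle."""
        t1 = trimesh.creation.cylinder(radius=5.0, height=40.0, sections=64)
        t2 = t1.copy()
        t1.apply_translation([-15, 0, 0])
        t2.apply_translation([15, 0, 0])
        mesh = trimesh.util.concatenate([t1, t2])
        plane = Plane(origin=[0, 0, 0], normal=[0, 0, 1])
        sec = slice_mesh(mesh, plane, anchor=[-15, 0, 0])
        poly = Polygon(sec.coords2d)
        anchor2d = plane.to_plane_coords([-15, 0, 0])[0]
        other2d = plane.to_plane_coords([15, 0, 0])[0]
        from shapely.geometry import Point
        assert poly.contains(Point(anchor2d))
        assert not poly.contains(Point(other2d))
        assert abs(sec.area - np.pi * 25) / (np.pi * 25) < 0.01

    def test_plane_missing_mesh_raises(self):
        mesh = _fine_cylinder()
        with pytest.raises(EmptySectionError):
            slice_mesh(mesh, Plane(origin=[0, 0, 100], normal=[0, 0, 1]),
                       anchor=[0, 0, 100])

    def test_contour_is_ccw_and_planar(self):
        mesh = _fine_cylinder()
        plane = Plane(origin=[0, 0, 3], normal=[0, 0, 1])
        sec = slice_mesh(mesh, plane, anchor=[0, 0, 3])
        assert polygon_area(sec.coords2d) > 0  # CCW about the normal
        assert np.abs(plane.signed_distance(sec.contour)).max() < 1e-6


class TestMinMaxDiameters:
    def test_circle(self):
        mesh = _fine_cylinder()
        sec = slice_mesh(mesh, Plane(origin=[0, 0, 0], normal=[0, 0, 1]),
                         anchor=[0, 0, 0])
        d_min, d_max, _, _ = min_max_diameters(sec)
        assert abs(d_min - 20.0) / 20.0 < 1e-3
        assert abs(d_max - 20.0) / 20.0 < 1e-3

    def test_ellipse_axes(self):
        """Center chords of an ellipse are extremized on its axes."""
        mesh = _fine_cylinder()
        mesh.apply_scale([1.5, 1.0, 1.0])  # semi-axes 15 x 10
        sec = slice_mesh(mesh, Plane(origin=[0, 0, 0], normal=[0, 0, 1]),
                         anchor=[0, 0, 0])
        d_min, d_max, th_min, th_max = min_max_diameters(sec)
        assert abs(d_min - 20.0) / 20.0 < 0.002
        assert abs(d_max - 30.0) / 30.0 < 0.002

    def test_random_convex_polygon_matches_fine_scan(self, rng):
        """0.5° scan within 0.05 mm of the 0.01° brute-force oracle."""
        for _ in range(5):
            angles = np.sort(rng.uniform(0, 2 * np.pi, size=24))
            radii = rng.uniform(8.0, 12.0, size=24)
            pts2 = np.column_stack([radii * np.cos(angles),
                                    radii * np.sin(angles)])
            hull = Polygon(pts2).convex_hull
            xy = np.asarray(hull.exterior.coords)[:-1]
            contour = np.column_stack([xy, np.zeros(len(xy))])
            sec = CrossSection(contour=contour,
                               plane=Plane(origin=[0, 0, 0],
                                           normal=[0, 0, 1]))
            d_min, d_max, _, _ = min_max_diameters(sec, angular_step=0.5)
            o_min, o_max, _, _ = min_max_diameters(sec, angular_step=0.01)
            assert abs(d_min - o_min) < 0.05
            assert abs(d_max - o_max) < 0.05

    def test_invalid_step_rejected(self):
        mesh = _fine_cylinder()
        sec = slice_mesh(mesh, Plane(origin=[0, 0, 0], normal=[0, 0, 1]),
                         anchor=[0, 0, 0])
        with pytest.raises(ValidationError):
            min_max_diameters(sec, angular_step=2.0)


class TestDerivedDiameters:
    def test_closed_forms(self):
        d_area, _ = derived_diameters(490.87385, 78.5398)
        assert abs(d_area - 25.0) < 1e-4
        _, d_perim = derived_diameters(490.87385, 78.5398)
        assert abs(d_perim - 25.0) < 1e-4

    def test_isoperimetric_ordering(self, rng):
        """d_perim >= d_area for every simple polygon; equality only in the
        circular limit."""
        for _ in range(20):
            n = int(rng.integers(6, 40))
            angles = np.sort(rng.uniform(0, 2 * np.pi, size=n))
            radii = rng.uniform(5.0, 15.0, size=n)
            xy = np.column_stack([radii * np.cos(angles),
                                  radii * np.sin(angles)])
            area = abs(polygon_area(xy))
            perim = polygon_perimeter(xy)
            d_area, d_perim = derived_diameters(area, perim)
            assert d_perim >= d_area - 1e-12

    def test_non_positive_rejected(self):
        with pytest.raises(ValidationError):
            derived_diameters(-1.0, 10.0)


class TestPolygonOracle:
    def test_matches_shapely_on_random_polygons(self, rng):
        """Shoelace area/perimeter/centroid within 1e-9 relative of the
        independent shapely oracle on 100 random star-shaped polygons."""
        for _ in range(100):
            n = int(rng.integers(5, 60))
            angles = np.sort(rng.uniform(0, 2 * np.pi, size=n))
            radii = rng.uniform(2.0, 20.0, size=n)
            xy = np.column_stack([radii * np.cos(angles),
                                  radii * np.sin(angles)])
            poly = Polygon(xy)
            assert poly.is_valid
            a = abs(polygon_area(xy))
            assert abs(a - poly.area) <= 1e-9 * poly.area
            p = polygon_perimeter(xy)
            assert abs(p - poly.exterior.length) <= 1e-9 * poly.exterior.length
            c = polygon_centroid(xy)
            sc = np.array([poly.centroid.x, poly.centroid.y])
            assert np.linalg.norm(c - sc) <= 1e-9 * max(1.0, np.abs(sc).max())


class TestAreaProfile:
    @staticmethod
    def _axis_centerline(z0=-35.0, z1=35.0):
        return Centerline(points=[[0, 0, z0], [0, 0, z1]])

    def test_cylinder_profile_flat(self):
        mesh = _fine_cylinder(sections=256)
        cl = self._axis_centerline()
        prof = area_profile(mesh, cl, 20.0, 40.0, spacing=1.0)
        assert len(prof) == 21
        areas = np.array([st.area for st in prof])
        np.testing.assert_allclose(areas, R10_AREA, rtol=0.005)

    def test_bulge_argmax_location(self, default_phantom):
        """The profile's peak lands within one station of the phantom's
        sinus-bulge belly."""
        mesh, landmarks, truth = default_phantom
        spec = truth.spec
        cl = Centerline(points=spec.axis_point(
            np.linspace(0, spec.total_length, 300)))
        s0 = spec.s_annulus
        prof = area_profile(mesh, cl, s0, s0 + 30.0, spacing=1.0)
        areas = np.array([st.area for st in prof])
        s_peak = prof[int(np.argmax(areas))].s - s0
        assert abs(s_peak - spec.bulge_center_mm) <= 1.0

    def test_rigid_invariance_of_profile(self, rng):
        mesh = _fine_cylinder(sections=128)
        cl = self._axis_centerline()
        ref = [st.area for st in area_profile(mesh, cl, 10, 30, 1.0)]
        R, t = random_rigid(rng)
        mesh2 = apply_rigid(mesh, R, t)
        cl2 = Centerline(points=cl.points @ R.T + t)
        got = [st.area for st in area_profile(mesh2, cl2, 10, 30, 1.0)]
        np.testing.assert_allclose(got, ref, rtol=1e-6)

    def test_mostly_missing_profile_raises(self):
        mesh = _fine_cylinder()
        cl = Centerline(points=[[0, 0, 0], [0, 0, 200]])
        with pytest.raises(GeometryError, match="missing"):
            area_profile(mesh, cl, 0.0, 150.0, spacing=1.0)


def test_mesh_resolution_convergence():
    """Cylinder area error decreases monotonically with 4x face refinement
    and is below 0.1% for a >= 20k-face mesh."""
    errors = []
    for sections in (16, 64, 256):
        mesh = trimesh.creation.cylinder(radius=10.0, height=80.0,
                                         sections=sections)
        sec = slice_mesh(mesh, Plane(origin=[0, 0, 0], normal=[0, 0, 1]),
                         anchor=[0, 0, 0])
        errors.append(abs(sec.area - R10_AREA) / R10_AREA)
    assert errors[0] > errors[1] > errors[2]
    big = trimesh.creation.cylinder(radius=10.0, height=80.0, sections=5001)
    assert len(big.faces) >= 20000
    sec = slice_mesh(big, Plane(origin=[0, 0, 0], normal=[0, 0, 1]),
                     anchor=[0, 0, 0])
    assert abs(sec.area - R10_AREA) / R10_AREA < 0.001
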