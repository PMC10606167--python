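"""Anatomical planes, sinus diameters, coronary heights, full pipeline."""

import numpy as np
import pytest

from conftest import random_rigid
from tavimetrics.centerline import Centerline
from tavimetrics.cross_section import Plane, ProfileStation, slice_mesh
from tavimetrics.errors import GeometryError, StageError, ValidationError
from tavimetrics.io import LandmarkSet
from tavimetrics.measure import (
    PipelineConfig,
    annulus_plane,
    coronary_height,
    find_sov_sntj,
    lvot_plane,
    run_pipeline,
    sinus_diameters,
)
from tavimetrics.phantom import PhantomSpec, generate_phantom


def _axis_cl(z0=0.0, z1=80.0):
    return Centerline(points=[[0, 0, z0], [0, 0, z1]])


class TestAnnulusPlane:
    NADIRS = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float)

    def test_plane_through_nadirs(self):
        plane = annulus_plane(self.NADIRS * 10, _axis_cl())
        np.testing.assert_allclose(plane.normal, [0, 0, 1], atol=1e-12)
        np.testing.assert_allclose(plane.origin,
                                   self.NADIRS.mean(axis=0) * 10)

    def test_normal_follows_centerline_direction(self):
        plane = annulus_plane(self.NADIRS * 10, _axis_cl(80.0, 0.0))
        np.testing.assert_allclose(plane.normal, [0, 0, -1], atol=1e-12)

    def test_tilted_nadir_plane_recovered(self):
        tilt = np.deg2rad(10.0)
        R = np.array([[1, 0, 0],
                      [0, np.cos(tilt), -np.sin(tilt)],
                      [0, np.sin(tilt), np.cos(tilt)]])
        nadirs = (self.NADIRS * 12.0) @ R.T
        plane = annulus_plane(nadirs, _axis_cl())
        expected = R @ np.array([0, 0, 1.0])
        angle = np.degrees(np.arccos(np.clip(
            abs(np.dot(plane.normal, expected)), -1, 1)))
        assert angle < 0.01

    def test_degenerate_nadirs_rejected(self):
        nadirs = np.array([[0, 0, 0], [1, 0, 0], [2, 0.001, 0]])
        with pytest.raises(GeometryError, match="implausible"):
            annulus_plane(nadirs, _axis_cl())


class TestLvotPlane:
    def test_offset_along_straight_centerline(self):
        ann = Plane(origin=[0, 0, 40], normal=[0, 0, 1])
        lv = lvot_plane(ann, _axis_cl(), offset=4.0)
        np.testing.assert_allclose(lv.origin, [0, 0, 36], atol=1e-9)
        np.testing.assert_allclose(lv.normal, ann.normal)

    def test_zero_offset_is_identity_station(self):
        ann = Plane(origin=[0, 0, 40], normal=[0, 0, 1])
        lv = lvot_plane(ann, _axis_cl(), offset=0.0)
        np.testing.assert_allclose(lv.origin, [0, 0, 40], atol=1e-9)

    def test_curved_chord_not_longer_than_arc(self):
        theta = np.linspace(0, np.pi / 2, 400)
        pts = np.column_stack([60 * (1 - np.cos(theta)),
                               np.zeros_like(theta), 60 * np.sin(theta)])
        cl = Centerline(points=pts)
        origin = cl.point_at(40.0)
        ann = Plane(origin=origin, normal=cl.tangent_at(40.0))
        lv = lvot_plane(ann, cl, offset=4.0)
        assert np.linalg.norm(lv.origin - ann.origin) <= 4.0 + 1e-6

    def test_too_short_centerline_rejected(self):
        ann = Plane(origin=[0, 0, 2], normal=[0, 0, 1])
        with pytest.raises(ValidationError):
            lvot_plane(ann, _axis_cl(), offset=4.0)


def _profile_from_areas(s0, areas):
    return [ProfileStation(s=s0 + i, area=a, section=None)
            for i, a in enumerate(areas)]


class _FakeStation(ProfileStation):
    @property
    def missing(self):
        return False


def _fake_profile(s0, areas):
    return [_FakeStation(s=float(s0 + i), area=float(a), section=object())
            for i, a in enumerate(areas)]


class TestFindSovSntj:
    def test_bulge_peak_and_plateau(self):
        s = np.arange(0.0, 30.0)
        areas = 500 + 120 * np.exp(-0.5 * ((s - 10) / 3.0) ** 2)
        areas[18:] = areas[18]  # exact plateau from 18 on
        qc = []
        s_sov, s_sntj = find_sov_sntj(_fake_profile(40.0, areas), 40.0,
                                      qc_flags=qc)
        assert s_sov == 50.0
        assert 40.0 + 15 <= s_sntj <= 40.0 + 19
        assert qc == []

    def test_monotone_cone_flags_boundary(self):
        areas = np.linspace(600, 300, 25)  # argmax at the first station
        qc = []
        find_sov_sntj(_fake_profile(0.0, areas), 0.0, qc_flags=qc)
        assert "SOV at search boundary" in qc

    def test_no_plateau_falls_back_with_flag(self):
        s = np.arange(0.0, 20.0)
        areas = 800 - 25 * s  # steep decline, never stabilizes at 2%
        qc = []
        s_sov, s_sntj = find_sov_sntj(_fake_profile(0.0, areas), 0.0,
                                      qc_flags=qc)
        assert any("stabilization" in f for f in qc)
        assert s_sntj > s_sov

    def test_too_few_stations_rejected(self):
        with pytest.raises(GeometryError):
            find_sov_sntj(_fake_profile(0.0, [500, 600, 550]), 0.0)


class TestSinusDiameters:
    @staticmethod
    def _circular_section(radius=17.0, z=10.0, n=720):
        phi = np.linspace(0, 2 * np.pi, n, endpoint=False)
        contour = np.column_stack([radius * np.cos(phi),
                                   radius * np.sin(phi),
                                   np.full(n, z)])
        from tavimetrics.cross_section import CrossSection
        return CrossSection(contour=contour,
                            plane=Plane(origin=[0, 0, z], normal=[0, 0, 1]))

    @staticmethod
    def _landmarks():
        return LandmarkSet(
            nadir_left=[0.0, 12.5, 0.0],
            nadir_right=[-10.825, -6.25, 0.0],
            nadir_noncoronary=[10.825, -6.25, 0.0],
            left_coronary_ostium=[0, 14, 14],
            right_coronary_ostium=[-12, -7, 12],
        )

    def test_circle_all_diameters_equal_2r(self):
        sec = self._circular_section()
        res = sinus_diameters(sec, self._landmarks())
        for d in (res.lcc, res.rcc, res.ncc):
            assert abs(d - 34.0) / 34.0 < 0.002

    def test_unequal_lobes_ordering(self):
        """Sinus diameters follow the per-lobe peak radii of an asymmetric
        phantom: lcc (18) > ncc (17) > rcc (16)."""
        spec = PhantomSpec(sinus_peak_lcc=18.0, sinus_peak_rcc=16.0,
                           sinus_peak_ncc=17.0)
        mesh, landmarks, truth = generate_phantom(spec)
        assert truth.report.sov.diameter_lcc > truth.report.sov.diameter_ncc \
            > truth.report.sov.diameter_rcc
        # measured on the mesh at the true SOV plane
        s_sov = spec.s_annulus + truth.sov_height_mm
        plane = Plane(origin=spec.axis_point(s_sov),
                      normal=spec.axis_frame(s_sov)[0])
        sec = slice_mesh(mesh, plane, anchor=spec.axis_point(s_sov))
        res = sinus_diameters(sec, landmarks)
        assert res.lcc > res.ncc > res.rcc
        for got, want in [(res.lcc, truth.report.sov.diameter_lcc),
                          (res.rcc, truth.report.sov.diameter_rcc),
                          (res.ncc, truth.report.sov.diameter_ncc)]:
            assert abs(got - want) / want < 0.01

    def test_rigid_invariance(self, rng):
        sec = self._circular_section()
        lm = self._landmarks()
        ref = sinus_diameters(sec, lm)
        R, t = random_rigid(rng)
        from tavimetrics.cross_section import CrossSection
        sec2 = CrossSection(contour=sec.contour @ R.T + t,
                            plane=Plane(origin=R @ np.array(sec.plane.origin) + t,
                                        normal=R @ sec.plane.normal))
        lm2 = lm.transformed(R, t)
        got = sinus_diameters(sec2, lm2)
        for a, b in [(got.lcc, ref.lcc), (got.rcc, ref.rcc),
                     (got.ncc, ref.ncc)]:
            assert abs(a - b) / b < 1e-6

    def test_nadir_on_centroid_rejected(self):
        sec = self._circular_section()
        lm = self._landmarks()
        bad = LandmarkSet(**{**lm.as_dict(), "nadir_left": [0.0, 0.02, 0.0]})
        with pytest.raises(GeometryError, match="undefined"):
            sinus_diameters(sec, bad)


class TestCoronaryHeight:
    PLANE = Plane(origin=[0, 0, 0], normal=[0, 0, 1])

    def test_perpendicular_height(self):
        assert coronary_height([5, -3, 12], self.PLANE) == pytest.approx(12.0)

    def test_in_plane_point_is_zero(self):
        assert coronary_height([7, 2, 0], self.PLANE) == pytest.approx(0.0)

    def test_signed_below_plane(self):
        assert coronary_height([0, 0, -5], self.PLANE) == pytest.approx(-5.0)


class TestPipeline:
    def test_default_phantom_full_report(self, default_report):
        flat = default_report.flat()
        assert len(flat) == 22
        assert all(np.isfinite(v) for v in flat.values())
        assert default_report.metadata["qc_flags"] == []

    def test_phantom_recovery_within_tolerances(self, default_phantom,
                                                default_report):
        _, _, truth = default_phantom
        t = truth.report
        r = default_report
        assert abs(r.annulus.area - t.annulus.area) / t.annulus.area < 0.005
        assert abs(r.coronary.height_left - t.coronary.height_left) < 0.2
        assert abs(r.coronary.height_right - t.coronary.height_right) < 0.2
        md = default_report.metadata
        sov_h = md["s_sov_mm"] - md["s_annulus_mm"]
        assert abs(sov_h - truth.sov_height_mm) <= 1.0
        for key in ("diameter_lcc", "diameter_rcc", "diameter_ncc"):
            got, want = getattr(r.sov, key), getattr(t.sov, key)
            assert abs(got - want) / want < 0.01

    def test_collinear_nadirs_fail_at_annulus_stage(self, default_phantom):
        mesh, landmarks, _ = default_phantom
        d = landmarks.as_dict()
        # nearly collinear nadirs (triangle area < 1 mm²) pass LandmarkSet
        # validation but must be refused by the annulus-plane stage
        d["nadir_left"] = [0.0, 0.0, 60.0]
        d["nadir_right"] = [5.0, 0.001, 60.0]
        d["nadir_noncoronary"] = [10.0, 0.0, 60.0]
        bad = LandmarkSet(**d)
        with pytest.raises(StageError) as err:
            run_pipeline(mesh, bad)
        assert err.value.stage == "annulus_plane"

    def test_nadir_error_couples_into_lvot(self, default_phantom):
        """Perturbing one nadir tilts the annulus plane, and the LVOT plane
        normal must follow it exactly (pure translation coupling)."""
        mesh, landmarks, _ = default_phantom
        d = landmarks.as_dict()
        d["nadir_left"] = list(np.asarray(d["nadir_left"]) + [0, 1.5, 1.0])
        perturbed = LandmarkSet(**d)
        from tavimetrics.centerline import extract_centerline_lbc
        cl = extract_centerline_lbc(mesh)
        from tavimetrics.centerline import orient_centerline
        cl, _ = orient_centerline(cl, perturbed.nadir_centroid())
        ann = annulus_plane(perturbed.nadirs(), cl)
        lv = lvot_plane(ann, cl, offset=4.0)
        np.testing.assert_array_equal(lv.normal, ann.normal)

    def test_unknown_config_key_rejected(self):
        with pytest.raises(ValidationError, match="unknown"):
            PipelineConfig.from_dict({"plane_spacing": 1.0})

    def test_allow_partial_emits_marked_report(self, default_phantom):
        """With a search range too short for the SOV/SNTJ hunt, a partial
        run still reports the annulus block and marks the missing stages."""
        mesh, landmarks, _ = default_phantom
        cfg = PipelineConfig(allow_partial=True, sov_search_max_mm=3.0)
        rep = run_pipeline(mesh, landmarks, cfg)
        assert rep.metadata.get("partial") is True
        assert np.isfinite(rep.annulus.area)
        assert np.isnan(rep.sov.diameter_lcc)
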