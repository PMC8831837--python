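"""Vessel-arm ray fitting, intersection, and inter-arm angles."""

import math

import numpy as np
import pytest

from ropvessel import (
    VesselRay,
    disc_center_angle,
    fit_vessel_ray,
    intersect_rays,
    make_eye_phantom,
    measure_eye,
    render_phantom,
    track_centerline,
    vessel_angle,
)
from ropvessel.errors import (
    DegenerateFitError,
    EmptyMeasurementError,
    ParallelLinesError,
)
from ropvessel.io import to_internal

from conftest import NOISE_5PCT


def ray(px, py, dx, dy):
    return VesselRay(anchor=np.array([px, py]), direction=np.array([dx, dy]),
                     fit_residual=0.0)


class TestFitVesselRay:
    def test_collinear_points_zero_residual(self):
        t = np.linspace(0, 60, 31)
        pts = np.column_stack([10 + t * 0.8, 20 + t * 0.6])
        r = fit_vessel_ray(pts)
        assert r.fit_residual < 1e-9
        assert abs(r.direction @ np.array([0.8, 0.6])) == pytest.approx(1.0)

    def test_reversed_input_same_oriented_ray(self):
        t = np.linspace(0, 60, 31)
        pts = np.column_stack([10 + t * 0.8, 20 + t * 0.6])
        r1 = fit_vessel_ray(pts)
        r2 = fit_vessel_ray(pts[::-1])
        # the line is identical; orientation follows each input's
        # proximal-to-distal order
        np.testing.assert_allclose(np.abs(r1.direction @ r2.direction), 1.0)
        np.testing.assert_allclose(r2.direction, -r1.direction, atol=1e-12)

    def test_tracked_arm_at_25_degrees_recovered(self):
        from ropvessel import PhantomSpec, straight_arm
        a = math.radians(25.0)
        arm = straight_arm((60, 80), (60 + 300 * math.cos(a), 80 + 300 * math.sin(a)), 5.0)
        raw, truth = render_phantom(PhantomSpec(arms=[arm], image_size=(300, 450),
                                                blur_sigma=1.0))
        img = to_internal(raw)
        tr = track_centerline(img, truth.arms[0]["seed"], truth.arms[0]["target"])
        r = fit_vessel_ray(tr.points, fit_span=50.0)
        ang = math.degrees(math.atan2(r.direction[1], r.direction[0]))
        assert ang == pytest.approx(25.0, abs=0.5)

    def test_coincident_points_degenerate(self):
        with pytest.raises(DegenerateFitError):
            fit_vessel_ray(np.tile([5.0, 5.0], (4, 1)))


class TestIntersectRays:
    def test_diagonal_lines_meet_at_origin(self):
        a = ray(-1, -1, 1, 1)
        b = ray(-1, 1, 1, -1)
        np.testing.assert_allclose(intersect_rays(a, b), [0.0, 0.0], atol=1e-12)

    def test_parallel_lines_raise(self):
        with pytest.raises(ParallelLinesError):
            intersect_rays(ray(0, 0, 1, 0.2), ray(0, 5, 1, 0.2))

    def test_intersection_satisfies_both_line_equations(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            p1, p2 = rng.uniform(-50, 50, 2), rng.uniform(-50, 50, 2)
            a1, a2 = rng.uniform(0, math.pi, 2)
            if abs(math.sin(a1 - a2)) < 0.05:
                continue
            a = ray(*p1, math.cos(a1), math.sin(a1))
            b = ray(*p2, math.cos(a2), math.sin(a2))
            v = intersect_rays(a, b)
            for r in (a, b):
                rel = v - r.anchor
                assert abs(rel[0] * r.direction[1] - rel[1] * r.direction[0]) < 1e-9


class TestVesselAngle:
    def test_perpendicular_rays_give_90(self):
        a = ray(10, 0, 1, 0)
        b = ray(0, 10, 0, 1)
        assert vessel_angle(a, b).angle_deg == pytest.approx(90.0)

    def test_obtuse_angle_not_folded(self):
        a = ray(10, 0, 1, 0)
        b = ray(10 * math.cos(math.radians(120)), 10 * math.sin(math.radians(120)),
                math.cos(math.radians(120)), math.sin(math.radians(120)))
        assert vessel_angle(a, b).angle_deg == pytest.approx(120.0)

    def test_symmetric_in_arguments(self):
        a = ray(5, 3, 0.6, 0.8)
        b = ray(-4, 6, 0.9, -0.43589)
        assert vessel_angle(a, b).angle_deg == vessel_angle(b, a).angle_deg

    def test_rotation_invariant(self):
        a = ray(10, 0, 1, 0)
        b = ray(0, 10, 0, 1)
        base = vessel_angle(a, b).angle_deg
        for phi in (17.0, 63.0, 141.0):
            c, s = math.cos(math.radians(phi)), math.sin(math.radians(phi))
            R = np.array([[c, -s], [s, c]])
            ar = VesselRay(R @ a.anchor, R @ a.direction, 0.0)
            br = VesselRay(R @ b.anchor, R @ b.direction, 0.0)
            assert vessel_angle(ar, br).angle_deg == pytest.approx(base, abs=1e-9)

    def test_no_rop_regime_angle_recovered(self):
        # phantom designed at the healthy-eye mean TAA of 122.4 degrees
        spec = make_eye_phantom(angle_artery=122.4, include_vein=False,
                                noise_sigma=NOISE_5PCT, seed=9)
        raw, truth = render_phantom(spec)
        m = measure_eye(to_internal(raw), truth.annotation())
        assert m.taa == pytest.approx(122.4, abs=1.0)


class TestMeasureEye:
    def test_full_eye_recovers_design_geometry(self, eye_phantom_clean):
        img, truth = eye_phantom_clean
        m = measure_eye(img, truth.annotation())
        assert m.taa == pytest.approx(110.0, abs=1.0)
        assert m.tva == pytest.approx(120.0, abs=1.0)
        assert m.taw == pytest.approx(4.0, abs=0.5)
        assert m.tvw == pytest.approx(6.0, abs=0.5)
        assert not m.taw_inferior_only and not m.tvw_inferior_only

    def test_missing_vein_pair_leaves_vein_fields_absent(self):
        spec = make_eye_phantom(include_vein=False)
        raw, truth = render_phantom(spec)
        m = measure_eye(to_internal(raw), truth.annotation())
        assert m.taa is not None and m.taw is not None
        assert m.tva is None and m.tvw is None

    def test_overlapped_superior_artery_uses_inferior_width_only(self):
        spec = make_eye_phantom(include_vein=False, superior_artery_overlapped=True)
        raw, truth = render_phantom(spec)
        m = measure_eye(to_internal(raw), truth.annotation())
        assert m.taa == pytest.approx(110.0, abs=1.0)  # angle still measured
        assert m.taw == pytest.approx(4.0, abs=0.5)
        assert m.taw_inferior_only

    def test_empty_annotation_raises(self, eye_phantom_clean):
        img, _ = eye_phantom_clean
        with pytest.raises(EmptyMeasurementError):
            measure_eye(img, {"vessels": []})

    def test_disc_center_chord_less_accurate_than_intersection(self):
        # arm lines intersect 15 px temporal to the disc center: the
        # chord-at-disc-center baseline mislocates the vertex, the
        # trace-back intersection does not
        spec = make_eye_phantom(angle_artery=110.0, include_vein=False,
                                intersection_offset=(15.0, 0.0))
        raw, truth = render_phantom(spec)
        img = to_internal(raw)
        m = measure_eye(img, truth.annotation())
        arms = {a["arm"]: a for a in truth.arms}
        chord = disc_center_angle(truth.disc_center, arms["superior"]["target"],
                                  arms["inferior"]["target"])
        assert abs(m.taa - 110.0) < abs(chord - 110.0)
        assert abs(chord - 110.0) > 1.0
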