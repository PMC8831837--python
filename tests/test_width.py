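"""Vessel caliber estimation: edge profiles, edge detection, widths."""

import numpy as np
import pytest
from skimage.transform import rescale

from ropvessel import (
    CenterlineTrace,
    PhantomSpec,
    WidthParams,
    aggregate_temporal_width,
    detect_edges,
    edge_profile,
    render_phantom,
    straight_arm,
    track_centerline,
    vessel_width,
)
from ropvessel.errors import (
    EndpointError,
    InsufficientMeasurementError,
    LowContrastError,
    MissingMeasurementError,
)
from ropvessel.io import to_internal
from ropvessel.width import EdgeProfile, WidthMeasurement

from conftest import NOISE_5PCT


def band_image_and_trace(half_width=3.0, bg=1.0, depth=1.0):
    """Analytic dark band: rows within half_width of y = 200.5 set to
    bg - depth; horizontal trace along the band axis."""
    img = np.full((400, 400), bg)
    yy = np.arange(400)
    img[np.abs(yy - 200.5) <= half_width, :] = bg - depth
    pts = np.column_stack([np.arange(150.0, 250.0, 2.0),
                           np.full(50, 200.5)])
    return img, CenterlineTrace(points=pts, converged=True)


class TestEdgeProfile:
    def test_dark_band_profile_shape(self):
        img, tr = band_image_and_trace()
        prof = edge_profile(img, tr, 25, max_offset=10.0)
        inner = np.abs(prof.offsets) < 2.0
        outer = np.abs(prof.offsets) > 5.0
        # cubic interpolation rings by a few percent at the hard step;
        # inside stays near the dark level, outside near the background
        assert prof.integrals[inner].max() < 0.1
        assert prof.integrals[outer].min() > 0.9
        top, bottom = detect_edges(prof)
        assert top == pytest.approx(-3.0, abs=0.25)
        assert bottom == pytest.approx(3.0, abs=0.25)

    def test_constant_image_flat_profile_low_contrast(self):
        img = np.full((400, 400), 0.5)
        _, tr = band_image_and_trace()
        prof = edge_profile(img, tr, 25)
        assert np.ptp(prof.integrals) < 1e-9
        with pytest.raises(LowContrastError):
            detect_edges(prof)

    def test_symmetric_phantom_profile_even(self, straight_phantom):
        img, truth = straight_phantom
        tr = track_centerline(img, truth.arms[0]["seed"], truth.arms[0]["target"])
        prof = edge_profile(img, tr, len(tr.points) // 2)
        sym_err = np.abs(prof.integrals - prof.integrals[::-1]).max()
        assert sym_err <= 0.02 * np.ptp(prof.integrals)

    def test_endpoint_raises(self):
        img, tr = band_image_and_trace()
        with pytest.raises(EndpointError):
            edge_profile(img, tr, 0)


class TestDetectEdges:
    @staticmethod
    def _ramp_profile(left_edge, right_edge, bg_left=1.0, bg_right=1.0,
                      center=0.0, ramp=1.0):
        off = np.arange(-8.0, 8.001, 0.25)
        # linear ramps of width `ramp` centered exactly at each edge
        y = (center
             + (bg_left - center) * np.clip((left_edge - off) / ramp + 0.5, 0, 1)
             + (bg_right - center) * np.clip((off - right_edge) / ramp + 0.5, 0, 1))
        return EdgeProfile(offsets=off, integrals=y)

    def test_symmetric_step_edges(self):
        prof = self._ramp_profile(-3.0, 3.0, center=0.0)
        top, bottom = detect_edges(prof)
        assert top == pytest.approx(-3.0, abs=0.25)
        assert bottom == pytest.approx(3.0, abs=0.25)

    def test_asymmetric_background_levels(self):
        prof = self._ramp_profile(-3.5, 2.5, bg_left=0.8, bg_right=1.2, center=0.0)
        top, bottom = detect_edges(prof)
        assert top == pytest.approx(-3.5, abs=0.25)
        assert bottom == pytest.approx(2.5, abs=0.25)

    def test_too_few_offsets_rejected(self):
        prof = EdgeProfile(offsets=np.array([-1.0, 0.0, 1.0]),
                           integrals=np.array([1.0, 0.0, 1.0]))
        with pytest.raises(Exception):
            detect_edges(prof)


class TestVesselWidth:
    def test_width_six_recovered_within_quarter_pixel(self, straight_phantom):
        img, truth = straight_phantom
        tr = track_centerline(img, truth.arms[0]["seed"], truth.arms[0]["target"])
        wm = vessel_width(img, tr)
        assert wm.mean_width == pytest.approx(6.0, abs=0.25)
        assert wm.mean_width == pytest.approx(np.mean(wm.per_position_widths))

    def test_measured_width_monotone_in_true_width(self):
        means = []
        for w in (4.0, 8.0):
            raw, truth = render_phantom(PhantomSpec(
                arms=[straight_arm((100, 150), (500, 260), w)],
                image_size=(400, 600), noise_sigma=NOISE_5PCT,
                blur_sigma=1.0, seed=2))
            img = to_internal(raw)
            tr = track_centerline(img, truth.arms[0]["seed"], truth.arms[0]["target"])
            means.append(vessel_width(img, tr).mean_width)
        assert means[0] < means[1]

    def test_arclength_capped_at_100(self, straight_phantom):
        img, truth = straight_phantom
        tr = track_centerline(img, truth.arms[0]["seed"], truth.arms[0]["target"])
        assert tr.total_arclength > 300
        wm = vessel_width(img, tr)
        assert wm.arclength_used <= 100.0

    def test_halfmax_and_gradient_agree_on_ideal_phantom(self, straight_phantom):
        img, truth = straight_phantom
        tr = track_centerline(img, truth.arms[0]["seed"], truth.arms[0]["target"])
        w_grad = vessel_width(img, tr, WidthParams(edge_method="gradient"))
        w_half = vessel_width(img, tr, WidthParams(edge_method="halfmax"))
        assert abs(w_grad.mean_width - w_half.mean_width) <= 0.5

    def test_gaussian_profile_halfmax_recovers_fwhm(self):
        raw, truth = render_phantom(PhantomSpec(
            arms=[straight_arm((100, 150), (500, 260), 6.0)],
            image_size=(400, 600), blur_sigma=0.5, vessel_profile="gaussian"))
        img = to_internal(raw)
        tr = track_centerline(img, truth.arms[0]["seed"], truth.arms[0]["target"])
        wm = vessel_width(img, tr, WidthParams(edge_method="halfmax"))
        assert wm.mean_width == pytest.approx(6.0, abs=0.5)

    def test_scale_consistency(self):
        raw, truth = render_phantom(PhantomSpec(
            arms=[straight_arm((80, 120), (420, 230), 5.0)],
            image_size=(350, 500), blur_sigma=1.0))
        img = to_internal(raw)
        tr = track_centerline(img, truth.arms[0]["seed"], truth.arms[0]["target"])
        w1 = vessel_width(img, tr).mean_width
        img2 = to_internal(rescale(raw, 2.0, order=3))
        tr2 = CenterlineTrace(points=tr.points * 2 + 0.5, converged=True)
        w2 = vessel_width(img2, tr2, WidthParams(max_offset=18.0)).mean_width
        assert w2 / w1 == pytest.approx(2.0, rel=0.05)

    def test_no_contrast_anywhere_raises(self):
        img = np.full((400, 400), 0.5)
        _, tr = band_image_and_trace()
        with pytest.raises(InsufficientMeasurementError):
            vessel_width(img, tr)


class TestAggregateTemporalWidth:
    @staticmethod
    def _wm(value):
        return WidthMeasurement(per_position_widths=np.full(5, value),
                                arclength_used=10.0)

    def test_both_arms_averaged(self):
        tw = aggregate_temporal_width(self._wm(4.0), self._wm(5.0))
        assert tw.value == pytest.approx(4.5)
        assert not tw.inferior_only

    def test_missing_superior_falls_back_to_inferior(self):
        tw = aggregate_temporal_width(None, self._wm(4.8))
        assert tw.value == pytest.approx(4.8)
        assert tw.inferior_only

    def test_both_absent_raises(self):
        with pytest.raises(MissingMeasurementError):
            aggregate_temporal_width(None, None)
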