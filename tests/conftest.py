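"""Shared phantom fixtures.

Phantoms are rendered once per session; everything is generated
programmatically at test time. Noise levels quoted as "5% of contrast"
mean ``noise_sigma = 0.05 * vessel_contrast`` with the default contrast
of 0.5, i.e. sigma = 0.025 in image units.
"""

import numpy as np
import pytest

from ropvessel import PhantomSpec, make_eye_phantom, render_phantom, straight_arm
from ropvessel.io import to_internal

NOISE_5PCT = 0.025  # 5% of the default vessel contrast (0.5)


def cross2(a, b):
    """z-component of the 2D cross product."""
    return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]


def perp_deviation(points, p0, direction):
    """Perpendicular distances of points from the line through p0."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    rel = np.asarray(points) - np.asarray(p0, dtype=float)
    return np.abs(rel[:, 0] * d[1] - rel[:, 1] * d[0])


@pytest.fixture(scope="session")
def straight_phantom():
    """Noise-free straight vessel, width 6, oblique orientation."""
    arm = straight_arm((100.0, 150.0), (500.0, 260.0), 6.0)
    spec = PhantomSpec(arms=[arm], image_size=(400, 600), blur_sigma=1.0)
    raw, truth = render_phantom(spec)
    return to_internal(raw), truth


@pytest.fixture(scope="session")
def eye_phantom_clean():
    """Noise-free four-vessel eye: artery pair 110 deg / 4 px, vein pair
    120 deg / 6 px."""
    spec = make_eye_phantom(angle_artery=110.0, angle_vein=120.0,
                            width_artery=4.0, width_vein=6.0)
    raw, truth = render_phantom(spec)
    return to_internal(raw), truth
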