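"""Synthetic fundus phantoms with known vessel geometry, and synthetic
measurement cohorts.

Phantoms emulate what the measurement pipeline actually sees in a
neonatal fundus photograph: dark curvilinear vessels of known width on a
brighter background with a bright mock optic disc, optical blur, and
i.i.d. Gaussian pixel noise. Each rendered image comes with its exact
ground truth (analytic centerlines, widths, inter-arm angles) and an
annotation dict directly consumable by :func:`ropvessel.angles.measure_eye`.

Vessel cross-sections are rendered with sub-pixel (area-coverage)
anti-aliasing so the true edge position is meaningful at fractions of a
pixel: the 'rect' profile is an ideal band of the nominal width, the
'gaussian' profile has its full width at half maximum equal to the
nominal width.

Cohort sampling draws per-stage normal (optionally jointly multivariate
normal) TAA/TVA/TAW/TVW values from specified group means and SDs,
emulating the per-stage summary distributions of a screening cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import InvalidSpecError

__all__ = [
    "ArmSpec",
    "PhantomSpec",
    "PhantomTruth",
    "render_phantom",
    "straight_arm",
    "sinusoid_arm",
    "make_eye_phantom",
    "GroupParams",
    "CohortSpec",
    "sample_cohort",
    "COHORT_VARIABLES",
]

COHORT_VARIABLES = ("taa", "tva", "taw", "tvw")


@dataclass
class ArmSpec:
    """One vessel arm: a centerline polyline and a nominal width."""

    polyline: np.ndarray          # (N, 2) points (x, y) along the axis
    width: float                  # pixels
    vessel: str = "artery"        # 'artery' | 'vein'
    arm: str = "superior"         # 'superior' | 'inferior'
    overlapped: bool = False      # annotation flag: exclude from width

    def __post_init__(self):
        self.polyline = np.atleast_2d(np.asarray(self.polyline, dtype=float))


@dataclass
class PhantomSpec:
    """Recipe for one synthetic fundus image."""

    arms: list
    image_size: tuple = (600, 800)        # (rows, cols)
    background_level: float = 0.82
    vessel_contrast: float = 0.5
    vessel_profile: str = "rect"          # 'rect' | 'gaussian'
    disc_center: tuple | None = None      # (x, y); None = no disc
    disc_radius: float = 40.0
    noise_sigma: float = 0.0
    blur_sigma: float = 1.0
    seed: int = 0


@dataclass
class PhantomTruth:
    """Ground truth paired with a rendered phantom."""

    arms: list                      # dicts: vessel, arm, width, axis, seed, target
    true_angle_artery: float | None = None
    true_angle_vein: float | None = None
    disc_center: tuple | None = None
    disc_radius: float | None = None
    vertex_artery: tuple | None = None
    vertex_vein: tuple | None = None

    def annotation(self, stage: str = "none", image: str = "") -> dict:
        """Annotation dict in the schema ``measure_eye`` consumes."""
        return {
            "schema_version": 1,
            "image": image,
            "stage": stage,
            "vessels": [
                {
                    "vessel": a["vessel"],
                    "arm": a["arm"],
                    "seed": [float(a["seed"][0]), float(a["seed"][1])],
                    "target": [float(a["target"][0]), float(a["target"][1])],
                    "overlapped": bool(a.get("overlapped", False)),
                }
                for a in self.arms
            ],
        }


def _densify(polyline: np.ndarray, spacing: float = 0.25) -> np.ndarray:
    seg = np.linalg.norm(np.diff(polyline, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] == 0:
        return polyline[:1]
    t = np.arange(0.0, s[-1] + spacing / 2, spacing)
    x = np.interp(t, s, polyline[:, 0])
    y = np.interp(t, s, polyline[:, 1])
    return np.column_stack([x, y])


def _point_at_arclength(polyline: np.ndarray, s_target: float) -> np.ndarray:
    seg = np.linalg.norm(np.diff(polyline, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    s_target = min(max(s_target, 0.0), s[-1])
    return np.array([
        np.interp(s_target, s, polyline[:, 0]),
        np.interp(s_target, s, polyline[:, 1]),
    ])


def render_phantom(spec: PhantomSpec) -> tuple[np.ndarray, PhantomTruth]:
    """Render a phantom image and return it with its ground truth.

    The returned image has fundus polarity (dark vessels, values near
    ``background_level`` elsewhere) as a float array; pass it through
    :func:`ropvessel.io.to_internal` before measurement. Rendering is
    deterministic in ``spec.seed``.
    """
    rows, cols = spec.image_size
    if rows < 16 or cols < 16:
        raise InvalidSpecError("image_size too small")
    if spec.vessel_contrast <= 0:
        raise InvalidSpecError("vessel_contrast must be positive")
    if spec.vessel_profile not in ("rect", "gaussian"):
        raise InvalidSpecError("vessel_profile must be 'rect' or 'gaussian'")
    if spec.noise_sigma < 0 or spec.blur_sigma < 0:
        raise InvalidSpecError("noise_sigma and blur_sigma must be >= 0")

    img = np.full((rows, cols), spec.background_level, dtype=float)

    if spec.disc_center is not None:
        cx, cy = spec.disc_center
        yy, xx = np.mgrid[0:rows, 0:cols]
        d = np.hypot(xx - cx, yy - cy)
        img += 0.12 * np.clip(spec.disc_radius - d + 0.5, 0.0, 1.0)

    depth = np.zeros_like(img)
    for a in spec.arms:
        if a.width <= 0:
            raise InvalidSpecError("arm width must be positive")
        poly = a.polyline
        if (poly[:, 0].min() < 0 or poly[:, 0].max() > cols - 1
                or poly[:, 1].min() < 0 or poly[:, 1].max() > rows - 1):
            raise InvalidSpecError("arm polyline extends outside the image")
        dense = _densify(poly)
        half = a.width / 2.0
        margin = half + 3.0 + 3.0 * spec.blur_sigma
        x0 = max(0, int(math.floor(poly[:, 0].min() - margin)))
        x1 = min(cols, int(math.ceil(poly[:, 0].max() + margin)) + 1)
        y0 = max(0, int(math.floor(poly[:, 1].min() - margin)))
        y1 = min(rows, int(math.ceil(poly[:, 1].max() + margin)) + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        d, _ = cKDTree(dense).query(pts, workers=-1)
        d = d.reshape(yy.shape)
        if spec.vessel_profile == "rect":
            # area-coverage anti-aliasing of an ideal band of width w
            f = np.clip(half - d + 0.5, 0.0, 1.0)
        else:
            sigma = a.width / (2.0 * math.sqrt(2.0 * math.log(2.0)))
            f = np.exp(-0.5 * (d / sigma) ** 2)
        depth[y0:y1, x0:x1] = np.maximum(depth[y0:y1, x0:x1], f)
    img -= spec.vessel_contrast * depth

    if spec.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, spec.blur_sigma)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sigma, img.shape)

    truth_arms = []
    by_vessel: dict[str, dict] = {}
    for a in spec.arms:
        s_total = float(np.sum(np.linalg.norm(np.diff(a.polyline, axis=0), axis=1)))
        entry = {
            "vessel": a.vessel,
            "arm": a.arm,
            "width": a.width,
            "axis": a.polyline.copy(),
            "seed": _point_at_arclength(a.polyline, 5.0),
            "target": _point_at_arclength(a.polyline, s_total - 5.0),
            "overlapped": a.overlapped,
        }
        truth_arms.append(entry)
        by_vessel.setdefault(a.vessel, {})[a.arm] = a

    def _pair_angle(vessel: str) -> float | None:
        arms = by_vessel.get(vessel, {})
        if "superior" not in arms or "inferior" not in arms:
            return None
        dirs = []
        for arm in ("superior", "inferior"):
            p = arms[arm].polyline
            d = p[-1] - p[0]
            dirs.append(d / np.linalg.norm(d))
        return math.degrees(math.acos(float(np.clip(np.dot(*dirs), -1, 1))))

    truth = PhantomTruth(
        arms=truth_arms,
        true_angle_artery=_pair_angle("artery"),
        true_angle_vein=_pair_angle("vein"),
        disc_center=spec.disc_center,
        disc_radius=spec.disc_radius if spec.disc_center is not None else None,
    )
    return img, truth


def straight_arm(p0, p1, width: float, vessel: str = "artery",
                 arm: str = "superior", **kw) -> ArmSpec:
    """Straight arm from p0 to p1."""
    return ArmSpec(polyline=np.array([p0, p1], dtype=float), width=width,
                   vessel=vessel, arm=arm, **kw)


def sinusoid_arm(x0: float, x1: float, y_center: float, amplitude: float,
                 period: float, width: float, vessel: str = "artery",
                 arm: str = "superior", phase: float = 0.0) -> ArmSpec:
    """Sinusoidal arm ``y = y_center + A sin(2 pi (x - x0)/period + phase)``."""
    x = np.linspace(x0, x1, max(64, int(abs(x1 - x0) * 2)))
    y = y_center + amplitude * np.sin(2 * math.pi * (x - x0) / period + phase)
    return ArmSpec(polyline=np.column_stack([x, y]), width=width,
                   vessel=vessel, arm=arm)


def make_eye_phantom(
    angle_artery: float = 110.0,
    angle_vein: float = 120.0,
    width_artery: float = 4.0,
    width_vein: float = 6.0,
    image_size: tuple = (700, 800),
    disc_center: tuple = (160.0, 350.0),
    disc_radius: float = 40.0,
    arm_length: float = 240.0,
    vein_vertex_offset: float = 60.0,
    intersection_offset: tuple = (0.0, 0.0),
    superior_artery_overlapped: bool = False,
    include_vein: bool = True,
    include_artery: bool = True,
    **render_kw,
) -> PhantomSpec:
    """Four-temporal-vessel eye phantom.

    Artery arms emanate symmetrically (half-angle ``angle_artery / 2``
    about the horizontal) from a vertex at ``disc_center +
    intersection_offset``; vein arms, slightly wider and at the larger
    ``angle_vein``, emanate from a vertex displaced ``vein_vertex_offset``
    px toward the nasal side so that the four arms stay separated over
    the measured span. ``intersection_offset`` displaces the artery
    vertex from the disc center to exercise the difference between the
    trace-back and disc-center angle methods.
    """
    vx = disc_center[0] + intersection_offset[0]
    vy = disc_center[1] + intersection_offset[1]
    arms = []

    def _radial_arm(vertex, half_angle_deg, sign, r0, r1, width, vessel, arm, overlapped=False):
        a = math.radians(half_angle_deg)
        d = np.array([math.cos(a), sign * math.sin(a)])
        p0 = np.asarray(vertex) + r0 * d
        p1 = np.asarray(vertex) + r1 * d
        return straight_arm(p0, p1, width, vessel=vessel, arm=arm, overlapped=overlapped)

    r0_a = disc_radius + 12.0
    if include_artery:
        arms.append(_radial_arm((vx, vy), angle_artery / 2, -1.0, r0_a,
                                r0_a + arm_length, width_artery, "artery", "superior",
                                overlapped=superior_artery_overlapped))
        arms.append(_radial_arm((vx, vy), angle_artery / 2, +1.0, r0_a,
                                r0_a + arm_length, width_artery, "artery", "inferior"))
    if include_vein:
        vvx, vvy = vx - vein_vertex_offset, vy
        r0_v = r0_a + vein_vertex_offset
        arms.append(_radial_arm((vvx, vvy), angle_vein / 2, -1.0, r0_v,
                                r0_v + arm_length, width_vein, "vein", "superior"))
        arms.append(_radial_arm((vvx, vvy), angle_vein / 2, +1.0, r0_v,
                                r0_v + arm_length, width_vein, "vein", "inferior"))

    spec = PhantomSpec(arms=arms, image_size=image_size, disc_center=disc_center,
                       disc_radius=disc_radius, **render_kw)
    return spec


# ---------------------------------------------------------------------------
# synthetic cohorts


@dataclass
class GroupParams:
    """Normal parameters of one ROP-stage group."""

    n: int
    mean: dict           # variable -> mean
    sd: dict             # variable -> sd


@dataclass
class CohortSpec:
    """Per-stage group sizes and normal parameters for the cohort
    variables, with an optional common correlation matrix."""

    groups: dict                       # stage label -> GroupParams
    correlation: np.ndarray | None = None
    variables: tuple = COHORT_VARIABLES
    seed: int = 0


def sample_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a synthetic per-eye measurement table.

    Within each stage group, variables are drawn i.i.d. normal with the
    group's mean/sd, or jointly multivariate normal when a correlation
    matrix is supplied (the same correlation in every group, scaled by
    the group SDs). Reproducible by ``spec.seed``.
    """
    variables = [v for v in spec.variables if v in next(iter(spec.groups.values())).mean]
    k = len(variables)
    corr = None
    if spec.correlation is not None:
        corr = np.asarray(spec.correlation, dtype=float)
        if corr.shape != (k, k) or not np.allclose(corr, corr.T):
            raise InvalidSpecError("correlation must be a symmetric k x k matrix")
        if np.min(np.linalg.eigvalsh(corr)) < -1e-10:
            raise InvalidSpecError("correlation matrix is not positive semi-definite")

    rng = np.random.default_rng(spec.seed)
    frames = []
    for stage, g in spec.groups.items():
        if g.n < 2:
            raise InvalidSpecError(f"group {stage!r} must have n >= 2")
        means = np.array([g.mean[v] for v in variables], dtype=float)
        sds = np.array([g.sd[v] for v in variables], dtype=float)
        if np.any(sds <= 0):
            raise InvalidSpecError("sds must be positive")
        if corr is None:
            draws = means + sds * rng.standard_normal((g.n, k))
        else:
            cov = corr * np.outer(sds, sds)
            L = np.linalg.cholesky(cov + 1e-12 * np.eye(k))
            draws = means + rng.standard_normal((g.n, k)) @ L.T
        df = pd.DataFrame(draws, columns=variables)
        df.insert(0, "stage", stage)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
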