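"""Temporal vessel angle from traced superior and inferior arms.

The superior and inferior arms of a vessel type (artery or vein) are
traced back toward the optic disc: a straight ray is fitted by total
least squares to the proximal span of each tracked centerline, the two
rays are extended to their intersection point (which need not coincide
with the disc center), and the inter-arm angle is the inverse cosine of
the dot product of the two distally oriented unit directions. Angles are
reported on (0, 180) degrees without folding, since stretched arcades in
healthy eyes give obtuse angles.

A disc-center chord baseline (angle subtended at the disc center) is
also provided; it is less faithful when the true intersection is
displaced from the disc center, which is the rationale for the
trace-back method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateFitError,
    EmptyMeasurementError,
    InvalidInputError,
    LowContrastError,
    NoVesselError,
    InsufficientMeasurementError,
    MissingMeasurementError,
    ParallelLinesError,
)
from .radon import as_intensity_image
from .tracking import TrackingParams, track_centerline
from .width import WidthParams, aggregate_temporal_width, vessel_width

__all__ = [
    "VesselRay",
    "AngleMeasurement",
    "EyeMeasurement",
    "fit_vessel_ray",
    "intersect_rays",
    "vessel_angle",
    "disc_center_angle",
    "measure_eye",
]


@dataclass
class VesselRay:
    """Fitted straight line for one vessel arm.

    ``direction`` is a unit vector oriented distally (away from the
    optic disc); ``anchor`` is the centroid of the fitted points;
    ``fit_residual`` is the RMS perpendicular distance of the points
    from the line.
    """

    anchor: np.ndarray
    direction: np.ndarray
    fit_residual: float

    def __post_init__(self):
        self.anchor = np.asarray(self.anchor, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        self.direction = d / np.linalg.norm(d)


@dataclass
class AngleMeasurement:
    """Inter-arm angle at the traced intersection point."""

    angle_deg: float
    vertex: np.ndarray
    ray_superior: VesselRay
    ray_inferior: VesselRay


def fit_vessel_ray(trace_points, fit_span: float = 50.0) -> VesselRay:
    """Total-least-squares ray through the proximal span of a trace.

    Points within ``fit_span`` of arclength from the proximal (first)
    point are used; the direction is the principal axis of the point
    cloud, oriented from proximal to distal.
    """
    pts = np.atleast_2d(np.asarray(trace_points, dtype=float))
    if len(pts) < 2:
        raise InvalidInputError("need at least 2 points to fit a ray")
    if fit_span <= 0:
        raise InvalidInputError("fit_span must be positive")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    sel = pts[s <= fit_span]
    if len(sel) < 2:
        sel = pts[:2]
    centroid = sel.mean(axis=0)
    centered = sel - centroid
    if np.allclose(centered, 0):
        raise DegenerateFitError("all points coincident")
    _, sv, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    if np.dot(direction, sel[-1] - sel[0]) < 0:
        direction = -direction
    resid = np.sqrt(np.mean((centered @ np.array([-direction[1], direction[0]])) ** 2))
    return VesselRay(anchor=centroid, direction=direction, fit_residual=float(resid))


def intersect_rays(a: VesselRay, b: VesselRay, parallel_tol: float = math.radians(0.5)) -> np.ndarray:
    """Intersection point of two infinite lines (may fall outside the
    image). Raises ParallelLinesError when the inter-line angle is below
    ``parallel_tol`` radians."""
    cross = a.direction[0] * b.direction[1] - a.direction[1] * b.direction[0]
    if abs(cross) < math.sin(parallel_tol):
        raise ParallelLinesError("rays are parallel within tolerance")
    diff = b.anchor - a.anchor
    t = (diff[0] * b.direction[1] - diff[1] * b.direction[0]) / cross
    return a.anchor + t * a.direction


def vessel_angle(a: VesselRay, b: VesselRay, parallel_tol: float = math.radians(0.5)) -> AngleMeasurement:
    """Angle between two vessel arms at their intersection.

    Both directions are re-anchored at the vertex pointing distally
    (toward each arm's fitted centroid) before taking the inverse cosine
    of their dot product; obtuse angles are reported as-is.
    """
    vertex = intersect_rays(a, b, parallel_tol)
    dirs = []
    for ray in (a, b):
        d = ray.direction.copy()
        toward = ray.anchor - vertex
        if np.linalg.norm(toward) > 1e-12 and np.dot(toward, d) < 0:
            d = -d
        dirs.append(d)
    cosang = float(np.clip(np.dot(dirs[0], dirs[1]), -1.0, 1.0))
    angle = math.degrees(math.acos(cosang))
    return AngleMeasurement(
        angle_deg=angle,
        vertex=vertex,
        ray_superior=VesselRay(a.anchor, dirs[0], a.fit_residual),
        ray_inferior=VesselRay(b.anchor, dirs[1], b.fit_residual),
    )


def disc_center_angle(disc_center, point_a, point_b) -> float:
    """Baseline: angle subtended at the disc center by two distal vessel
    points (the chord method used by earlier semi-automatic studies)."""
    c = np.asarray(disc_center, dtype=float)
    da = np.asarray(point_a, dtype=float) - c
    db = np.asarray(point_b, dtype=float) - c
    na, nb = np.linalg.norm(da), np.linalg.norm(db)
    if na == 0 or nb == 0:
        raise InvalidInputError("distal point coincides with disc center")
    cosang = float(np.clip(np.dot(da, db) / (na * nb), -1.0, 1.0))
    return math.degrees(math.acos(cosang))


@dataclass
class EyeMeasurement:
    """Per-eye temporal vessel geometry: TAA/TVA (degrees) and TAW/TVW
    (pixels), with provenance flags."""

    taa: float | None = None
    tva: float | None = None
    taw: float | None = None
    tvw: float | None = None
    taw_inferior_only: bool = False
    tvw_inferior_only: bool = False
    skipped_arms: list = field(default_factory=list)

    def is_empty(self) -> bool:
        return all(v is None for v in (self.taa, self.tva, self.taw, self.tvw))


def measure_eye(
    image,
    annotation: dict,
    tracking_params: TrackingParams | None = None,
    width_params: WidthParams | None = None,
    fit_span: float = 50.0,
) -> EyeMeasurement:
    """Measure TAA, TVA, TAW and TVW for one annotated eye.

    ``annotation`` follows the JSON annotation schema: a ``vessels``
    list of entries with ``vessel`` ('artery'|'vein'), ``arm``
    ('superior'|'inferior'), ``seed``/``target`` points, and an optional
    ``overlapped`` flag. An overlapped superior arm is excluded from the
    width aggregate (its inferior partner alone defines the temporal
    width) but still contributes to the angle.
    """
    img = as_intensity_image(image)
    tracking_params = tracking_params or TrackingParams()
    width_params = width_params or WidthParams()

    entries = {}
    for e in annotation.get("vessels", []):
        key = (e["vessel"], e["arm"])
        if key in entries:
            raise InvalidInputError(f"duplicate annotation entry for {key}")
        entries[key] = e

    result = EyeMeasurement()
    for vessel in ("artery", "vein"):
        traces = {}
        widths = {}
        for arm in ("superior", "inferior"):
            e = entries.get((vessel, arm))
            if e is None:
                continue
            try:
                tr = track_centerline(img, e["seed"], e["target"], tracking_params)
            except (NoVesselError, LowContrastError) as exc:
                result.skipped_arms.append((vessel, arm, str(exc)))
                continue
            traces[arm] = tr
            if e.get("overlapped"):
                result.skipped_arms.append((vessel, arm, "overlapped"))
                continue
            try:
                widths[arm] = vessel_width(img, tr, width_params)
            except (InsufficientMeasurementError, InvalidInputError) as exc:
                result.skipped_arms.append((vessel, arm, str(exc)))

        angle = None
        if "superior" in traces and "inferior" in traces:
            try:
                ray_s = fit_vessel_ray(traces["superior"].points, fit_span)
                ray_i = fit_vessel_ray(traces["inferior"].points, fit_span)
                angle = vessel_angle(ray_s, ray_i).angle_deg
            except (DegenerateFitError, ParallelLinesError) as exc:
                result.skipped_arms.append((vessel, "pair", str(exc)))
        width = None
        inferior_only = False
        if widths:
            try:
                tw = aggregate_temporal_width(
                    widths.get("superior"), widths.get("inferior")
                )
                width, inferior_only = tw.value, tw.inferior_only
            except MissingMeasurementError:
                pass
        if vessel == "artery":
            result.taa, result.taw = angle, width
            result.taw_inferior_only = inferior_only
        else:
            result.tva, result.tvw = angle, width
            result.tvw_inferior_only = inferior_only

    if result.is_empty():
        raise EmptyMeasurementError("no vessel pair could be measured")
    return result
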