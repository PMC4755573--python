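"""Registration features derived from a contour stack.

Two features drive the two registration steps:

* **Centerline** — per vessel, the area centroids of the 2D contours are
  lifted to 3D, interpolated with a cubic B-spline (chord-length
  parameterization, no smoothing) and resampled at a fixed arc-length
  interval (default 1 mm).  Centroids average out contour noise, so the
  centerline is the robust feature for the rigid step.

* **Surface samples** — per vessel, each contour is resampled to a fixed
  number of equal-arc-length vertices (rings), corresponding vertices across
  slices are interpolated along the stack with cubic B-splines, and
  intermediate rings are generated until the total sample count approaches a
  target (default 3500).  Surfaces carry the local detail the non-rigid step
  needs.

Both features inherit the vessel label of their generating contours; the
three vessels are built independently (labels partition the contours, and
the conditional matching never requires a connected centerline).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import make_interp_spline

from .exceptions import DegenerateGeometryError, ValidationError
from .types import Contour2D, ContourStack, LabeledPointSet, VesselLabel, signed_area

__all__ = [
    "polygon_centroid",
    "contour_centroid_3d",
    "Centerline",
    "SurfaceSamples",
    "extract_centerline",
    "build_surface_samples",
    "resample_closed_contour",
]

logger = logging.getLogger(__name__)

#: number of equal-arc-length vertices each ring is resampled to when
#: building surface samples.  Fixed so rings across slices are in vertex
#: correspondence.
RING_VERTICES = 32


def polygon_centroid(contour: Contour2D | np.ndarray) -> np.ndarray:
    """Area centroid of a closed polygon.

    Uses the shoelace form: with vertices (x_i, y_i), i = 0..N-1 and the
    closing convention (x_N, y_N) = (x_0, y_0),

        x_c = sum (x_i + x_{i+1}) (x_i y_{i+1} - x_{i+1} y_i) / (3 A2)
        y_c = sum (y_i + y_{i+1}) (x_i y_{i+1} - x_{i+1} y_i) / (3 A2)

    where A2 is the summed cross term (twice the signed area).  Numerator
    and denominator flip sign together under vertex-order reversal, so the
    result is independent of winding and of cyclic rotation of the list.
    """
    v = contour.vertices if isinstance(contour, Contour2D) else np.asarray(contour, dtype=float)
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    # math.fsum is exactly rounded, which makes the centroid bitwise
    # invariant to vertex-order reversal (every term negates) and to cyclic
    # rotation (same term multiset).
    a2 = math.fsum(cross)
    if abs(a2) < 1e-12:
        raise DegenerateGeometryError("polygon has zero signed area")
    cx = math.fsum((x + xn) * cross) / (3.0 * a2)
    cy = math.fsum((y + yn) * cross) / (3.0 * a2)
    return np.array([cx, cy])


def contour_centroid_3d(contour: Contour2D) -> np.ndarray:
    cx, cy = polygon_centroid(contour)
    return np.array([cx, cy, contour.z_mm])


@dataclass
class Centerline:
    """Resampled vessel centerlines (one polyline per vessel label)."""

    points: LabeledPointSet
    sample_interval_mm: float


@dataclass
class SurfaceSamples:
    """Interpolated lumen-surface sample set."""

    points: LabeledPointSet
    per_slice_count: int
    interpolated_slice_factor: int


def _chord_parameter(pts: np.ndarray) -> np.ndarray:
    """Cumulative chord length of a polyline; strictly increasing."""
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(seg <= 0):
        raise DegenerateGeometryError("coincident consecutive centroids")
    return np.concatenate([[0.0], np.cumsum(seg)])


def _fit_path_spline(u: np.ndarray, pts: np.ndarray):
    """Interpolating spline through ``pts``; cubic when >= 4 support points,
    linear fallback below that."""
    k = min(3, len(u) - 1)
    if k == 2:  # avoid even-order quirks; quadratic adds nothing here
        k = 1
    return make_interp_spline(u, pts, k=k)


def _arclength_resample(spl, u_end: float, interval: float, dense_per_unit: int = 10):
    """Sample a parametric curve at (approximately) equal arc intervals.

    Returns the samples and the total arc length.  The number of samples is
    round(L / interval) + 1 and they are equally spaced in arc length, so
    the realized spacing is within a half interval of the request.
    """
    n_dense = max(64, int(dense_per_unit * u_end / max(interval, 1e-9)) * 4)
    t = np.linspace(0.0, u_end, n_dense)
    d = np.asarray(spl(t))
    arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(d, axis=0), axis=1))])
    total = float(arc[-1])
    n_samples = max(2, int(round(total / interval)) + 1)
    targets = np.linspace(0.0, total, n_samples)
    t_at = np.interp(targets, arc, t)
    return np.asarray(spl(t_at)), total


def extract_centerline(stack: ContourStack, sample_interval_mm: float = 1.0) -> Centerline:
    """Extract the per-vessel centerline feature.

    Per vessel label, contour centroids (lifted to 3D with their slice z)
    are interpolated with a chord-length-parameterized cubic B-spline and
    resampled at ``sample_interval_mm``.  Vessels with fewer than 4 slices
    fall back to linear interpolation; vessels with fewer than 2 slices are
    skipped with a warning.
    """
    if not stack.is_fully_labeled():
        raise ValidationError("centerline extraction requires a fully labeled stack")
    if sample_interval_mm <= 0:
        raise ValidationError("sample_interval_mm must be positive")
    all_pts, all_labels = [], []
    for label in (VesselLabel.CCA, VesselLabel.ICA, VesselLabel.ECA):
        contours = stack.contours_for(label)
        if not contours:
            continue
        if len(contours) < 2:
            logger.warning("vessel %s has < 2 slices; skipped in centerline", label.name)
            continue
        centroids = np.array([contour_centroid_3d(c) for c in contours])
        u = _chord_parameter(centroids)
        spl = _fit_path_spline(u, centroids)
        samples, _ = _arclength_resample(spl, u[-1], sample_interval_mm)
        all_pts.append(samples)
        all_labels.append(np.full(len(samples), int(label), dtype=np.int8))
    if not all_pts:
        raise ValidationError("no vessel had enough slices for a centerline")
    return Centerline(
        LabeledPointSet(np.vstack(all_pts), np.concatenate(all_labels), role="centerline"),
        sample_interval_mm,
    )


def resample_closed_contour(contour: Contour2D, n: int = RING_VERTICES) -> np.ndarray:
    """Resample a closed contour to ``n`` equal-arc-length vertices.

    Orientation is normalized to counter-clockwise and the ring starts at
    the vertex of maximal x relative to the contour centroid, so rings of
    one vessel are in deterministic azimuthal correspondence across slices.
    """
    v = np.array(contour.vertices)
    if signed_area(v) < 0:
        v = v[::-1]
    c = polygon_centroid(v)
    start = int(np.argmax(v[:, 0] - c[0]))
    v = np.roll(v, -start, axis=0)
    closed = np.vstack([v, v[:1]])
    arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(closed, axis=0), axis=1))])
    total = arc[-1]
    if total <= 0:
        raise DegenerateGeometryError("contour has zero perimeter")
    targets = np.arange(n) * total / n
    x = np.interp(targets, arc, closed[:, 0])
    y = np.interp(targets, arc, closed[:, 1])
    return np.column_stack([x, y])


def build_surface_samples(
    stack: ContourStack,
    target_point_count: int = 3500,
    ring_vertices: int = RING_VERTICES,
) -> SurfaceSamples:
    """Build the interpolated lumen-surface sample set.

    Per vessel, contours are resampled to ``ring_vertices`` corresponding
    vertices, the rings are interpolated along the stack with cubic
    B-splines (chord-length parameter of the centroid path) and evaluated at
    enough intermediate positions that the total sample count across vessels
    is close to ``target_point_count``.  Ring counts are allocated to
    vessels proportionally to their centroid-path arc length.
    """
    if not stack.is_fully_labeled():
        raise ValidationError("surface construction requires a fully labeled stack")
    if target_point_count < ring_vertices:
        raise ValidationError("target_point_count must allow at least one ring")

    per_vessel: list[tuple[VesselLabel, np.ndarray, np.ndarray, float]] = []
    for label in (VesselLabel.CCA, VesselLabel.ICA, VesselLabel.ECA):
        contours = stack.contours_for(label)
        if not contours:
            continue
        rings = []
        centroids = []
        for c in contours:
            ring2d = resample_closed_contour(c, ring_vertices)
            rings.append(np.column_stack([ring2d, np.full(ring_vertices, c.z_mm)]))
            centroids.append(contour_centroid_3d(c))
        rings_arr = np.asarray(rings)  # (n_slices, ring_vertices, 3)
        centroids_arr = np.asarray(centroids)
        if len(contours) == 1:
            length = 0.0
            u = np.zeros(1)
        else:
            u = _chord_parameter(centroids_arr)
            length = float(u[-1])
        per_vessel.append((label, rings_arr, u, length))
    if not per_vessel:
        raise ValidationError("stack has no contours to build a surface from")

    total_length = sum(L for _, _, _, L in per_vessel)
    total_rings = max(1, target_point_count // ring_vertices)

    pts_out, labels_out = [], []
    max_factor = 1
    for label, rings_arr, u, length in per_vessel:
        n_slices = rings_arr.shape[0]
        if n_slices == 1:
            vessel_rings = rings_arr
        else:
            if total_length > 0:
                n_rings = max(2, int(round(total_rings * length / total_length)))
            else:
                n_rings = n_slices
            flat = rings_arr.reshape(n_slices, -1)
            spl = _fit_path_spline(u, flat)
            u_eval = np.linspace(0.0, u[-1], n_rings)
            vessel_rings = np.asarray(spl(u_eval)).reshape(n_rings, ring_vertices, 3)
            max_factor = max(max_factor, int(np.ceil(n_rings / n_slices)))
        pts = vessel_rings.reshape(-1, 3)
        pts_out.append(pts)
        labels_out.append(np.full(len(pts), int(label), dtype=np.int8))

    points = LabeledPointSet(np.vstack(pts_out), np.concatenate(labels_out), role="surface")
    return SurfaceSamples(points, per_slice_count=ring_vertices,
                          interpolated_slice_factor=max_factor)
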