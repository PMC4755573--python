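"""Centroid, centerline and surface-sample feature extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tacicp import (
    Contour2D,
    ContourStack,
    DegenerateGeometryError,
    RigidTransform,
    VesselLabel,
    build_surface_samples,
    extract_centerline,
    polygon_centroid,
)
from tacicp.features import resample_closed_contour

from conftest import random_star_polygon, regular_polygon
from oracles import rasterized_centroid


class TestPolygonCentroid:
    def test_unit_square(self):
        c = polygon_centroid(np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float))
        np.testing.assert_allclose(c, [0.5, 0.5], atol=1e-15)

    def test_right_triangle(self):
        c = polygon_centroid(np.array([[0, 0], [1, 0], [0, 1]], float))
        np.testing.assert_allclose(c, [1 / 3, 1 / 3], atol=1e-15)

    def test_order_reversal_exact_invariance(self, rng):
        for _ in range(20):
            v = random_star_polygon(rng)
            np.testing.assert_array_equal(polygon_centroid(v), polygon_centroid(v[::-1]))

    def test_cyclic_rotation_invariance(self, rng):
        v = random_star_polygon(rng, n=9)
        base = polygon_centroid(v)
        for k in range(1, 9):
            np.testing.assert_allclose(polygon_centroid(np.roll(v, k, axis=0)), base, atol=1e-12)

    def test_matches_rasterization_oracle_12gon(self, rng):
        v = random_star_polygon(rng, n=12, scale=1.0)
        c = polygon_centroid(v)
        oracle = rasterized_centroid(v, pitch=1e-3)
        assert np.linalg.norm(c - oracle) < 1e-3

    def test_centroid_inside_convex_polygon(self, rng):
        from matplotlib.path import Path

        for _ in range(20):
            v = regular_polygon(int(rng.integers(3, 12)), radius=float(rng.uniform(0.5, 4)),
                                center=rng.uniform(-3, 3, 2), phase=float(rng.uniform(0, 6)))
            assert Path(v).contains_point(polygon_centroid(v))

    def test_zero_area_raises(self):
        with pytest.raises((DegenerateGeometryError, Exception)):
            polygon_centroid(np.array([[0, 0], [1, 1], [2, 2]], float))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**32 - 1))
    def test_translation_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        v = random_star_polygon(rng)
        shift = rng.uniform(-10, 10, 2)
        np.testing.assert_allclose(
            polygon_centroid(v + shift), polygon_centroid(v) + shift, atol=1e-9
        )


class TestCenterline:
    def test_straight_tube_samples_on_axis(self, tiny_stack):
        # 5 slices is not enough; build a 10 mm tube at 1 mm spacing
        contours = [
            Contour2D(float(z), regular_polygon(16, radius=2.0), VesselLabel.CCA)
            for z in range(11)
        ]
        stack = ContourStack(contours, 1.0)
        cl = extract_centerline(stack, 1.0)
        assert len(cl.points) == 11
        np.testing.assert_allclose(cl.points.points[:, :2], 0.0, atol=1e-9)
        spacing = np.diff(np.sort(cl.points.points[:, 2]))
        np.testing.assert_allclose(spacing, 1.0, atol=1e-9)

    def test_helix_within_tolerance(self):
        # contour centroids on a helix of radius 10, pitch 12 mm
        zs = np.linspace(0, 24, 33)
        contours = []
        for z in zs:
            phi = 2 * np.pi * z / 12.0
            center = (10 * np.cos(phi), 10 * np.sin(phi))
            contours.append(Contour2D(float(z), regular_polygon(16, 1.0, center), VesselLabel.CCA))
        cl = extract_centerline(ContourStack(contours, float(zs[1] - zs[0])), 1.0)
        # distance of each sample to the analytic helix (dense polyline)
        td = np.linspace(0, 24, 20001)
        phid = 2 * np.pi * td / 12.0
        helix = np.column_stack([10 * np.cos(phid), 10 * np.sin(phid), td])
        from scipy.spatial import cKDTree

        d, _ = cKDTree(helix).query(cl.points.points)
        assert d.max() < 0.05

    def test_in_plane_rotation_equivariance(self, fast_phantom):
        angle = 17.0
        rot = RigidTransform.from_rotvec([0, 0, angle], [0, 0, 0])
        rotated = ContourStack(
            [
                Contour2D(c.z_mm, rot.apply(np.column_stack([c.vertices, np.zeros(c.n_vertices)]))[:, :2], c.label)
                for c in fast_phantom.contours
            ],
            fast_phantom.slice_spacing_mm,
        )
        cl = extract_centerline(fast_phantom, 1.0)
        cl_rot = extract_centerline(rotated, 1.0)
        np.testing.assert_allclose(cl_rot.points.points, rot.apply(cl.points.points), atol=1e-6)

    def test_unlabeled_stack_rejected(self):
        c = Contour2D(0.0, [[0, 0], [1, 0], [0, 1]])
        stack = ContourStack([c, Contour2D(1.0, [[0, 0], [1, 0], [0, 1]])], 1.0)
        with pytest.raises(Exception):
            extract_centerline(stack)


class TestSurfaceSamples:
    def test_cylinder_radius_preserved(self):
        contours = [
            Contour2D(float(z), regular_polygon(24, radius=3.0), VesselLabel.CCA)
            for z in range(5)
        ]
        surf = build_surface_samples(ContourStack(contours, 1.0), 500)
        r = np.linalg.norm(surf.points.points[:, :2], axis=1)
        np.testing.assert_allclose(r, 3.0, atol=0.05)

    def test_frustum_linear_radius(self):
        zs = np.arange(9, dtype=float)
        contours = [
            Contour2D(z, regular_polygon(32, radius=2.0 + 0.25 * z), VesselLabel.CCA)
            for z in zs
        ]
        surf = build_surface_samples(ContourStack(contours, 1.0), 800)
        pts = surf.points.points
        expected = 2.0 + 0.25 * pts[:, 2]
        r = np.linalg.norm(pts[:, :2], axis=1)
        # polygonal rings underestimate the circle slightly; compare against
        # the polygon's own chord radius profile
        poly_factor = np.linalg.norm(regular_polygon(32, 1.0)[0])
        np.testing.assert_allclose(r, expected * poly_factor, atol=0.05)

    def test_total_count_near_target(self, fast_phantom):
        for target in (800, 2000, 3500):
            surf = build_surface_samples(fast_phantom, target)
            assert 0.8 * target <= len(surf.points) <= 1.2 * target

    def test_labels_inherited(self, fast_phantom):
        surf = build_surface_samples(fast_phantom, 900)
        counts = surf.points.label_counts()
        assert set(counts) == {VesselLabel.CCA, VesselLabel.ICA, VesselLabel.ECA}
        assert all(v > 0 for v in counts.values())

    def test_ring_resampling_equal_arcs(self, rng):
        v = random_star_polygon(rng, n=20)
        ring = resample_closed_contour(Contour2D(0.0, v, VesselLabel.CCA), 32)
        assert ring.shape == (32, 2)
        closed = np.vstack([ring, ring[:1]])
        seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
        # equal arc steps along the polygon: segment lengths vary by < 50%
        # only where the polyline corners cut; mean spacing is consistent
        assert seg.max() < 3 * seg.mean()
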