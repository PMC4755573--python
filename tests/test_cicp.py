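"""Conditional ICP: conditional distance, match stage, rigid solve, loop."""

import math

import numpy as np
import pytest

from tacicp import (
    ConditionalWeightMatrix,
    DegenerateGeometryError,
    LabeledPoint,
    LabeledPointSet,
    UnmatchedLabelError,
    ValidationError,
    VesselLabel,
    conditional_distance,
    estimate_rigid,
    match_stage,
    run_cicp,
    extract_centerline,
)

from conftest import random_rigid
from oracles import brute_force_icp, brute_force_match, kabsch_oracle


def random_labeled_set(rng, n, labels=(0, 1, 2), scale=10.0, role="surface"):
    pts = rng.normal(0.0, scale, (n, 3))
    labs = rng.choice(labels, size=n)
    return LabeledPointSet(pts, labs, role)


class TestConditionalDistance:
    def test_identical_points_zero(self):
        p = LabeledPoint([1.0, 2.0, 3.0], VesselLabel.ICA)
        q = LabeledPoint([1.0, 2.0, 3.0], VesselLabel.ICA)
        assert conditional_distance(p, q, ConditionalWeightMatrix()) == 0.0

    def test_infinite_weight_between_branches(self):
        p = LabeledPoint([0.0, 0.0, 0.0], VesselLabel.ICA)
        q = LabeledPoint([2.0, 0.0, 0.0], VesselLabel.ECA)
        assert math.isinf(conditional_distance(p, q, ConditionalWeightMatrix(w2=math.inf)))

    def test_cca_branch_weight_one(self):
        p = LabeledPoint([0.0, 0.0, 0.0], VesselLabel.CCA)
        q = LabeledPoint([2.0, 0.0, 0.0], VesselLabel.ICA)
        assert conditional_distance(p, q, ConditionalWeightMatrix(w1=1.0)) == 2.0

    def test_infinite_weight_zero_distance_is_zero(self):
        p = LabeledPoint([1.0, 1.0, 1.0], VesselLabel.ICA)
        q = LabeledPoint([1.0, 1.0, 1.0], VesselLabel.ECA)
        assert conditional_distance(p, q, ConditionalWeightMatrix()) == 0.0

    def test_unlabeled_rejected(self):
        p = LabeledPoint([0.0, 0.0, 0.0], VesselLabel.UNLABELED)
        q = LabeledPoint([1.0, 0.0, 0.0], VesselLabel.CCA)
        with pytest.raises(ValidationError):
            conditional_distance(p, q, ConditionalWeightMatrix())


class TestWeightMatrix:
    def test_symmetry_and_lookup(self):
        W = ConditionalWeightMatrix(1.0, 2.0, math.inf)
        labs = (VesselLabel.CCA, VesselLabel.ICA, VesselLabel.ECA)
        for a in labs:
            assert W.weight(a, a) == 1.0
            for b in labs:
                assert W.weight(a, b) == W.weight(b, a)
        assert W.weight(VesselLabel.CCA, VesselLabel.ICA) == 2.0
        assert math.isinf(W.weight(VesselLabel.ICA, VesselLabel.ECA))

    def test_weight_constraints_enforced(self):
        with pytest.raises(ValidationError):
            ConditionalWeightMatrix(w0=0.0)
        with pytest.raises(ValidationError):
            ConditionalWeightMatrix(w0=2.0, w1=1.0)


class TestMatchStage:
    def test_matches_equal_exhaustive_oracle(self, rng):
        W = ConditionalWeightMatrix(1.0, 1.0, math.inf)
        for _ in range(25):
            m = random_labeled_set(rng, int(rng.integers(5, 50)))
            f = random_labeled_set(rng, int(rng.integers(5, 50)))
            corr = match_stage(m, f, W)
            idx, dist = brute_force_match(m.points, m.labels, f.points, f.labels, W.as_matrix())
            np.testing.assert_array_equal(corr.fixed_indices, idx)
            np.testing.assert_allclose(corr.distances, dist, atol=1e-12)

    def test_all_ones_equals_plain_nearest_neighbor(self, rng):
        from scipy.spatial.distance import cdist

        W = ConditionalWeightMatrix.ones()
        for _ in range(10):
            m = random_labeled_set(rng, 50)
            f = random_labeled_set(rng, 50)
            corr = match_stage(m, f, W)
            np.testing.assert_array_equal(
                corr.fixed_indices, np.argmin(cdist(m.points, f.points), axis=1)
            )

    def test_infinite_weight_excludes_nearer_branch(self):
        moving = LabeledPointSet([[0.0, 0.0, 0.0]], [int(VesselLabel.ICA)])
        fixed = LabeledPointSet(
            [[1.0, 0.0, 0.0], [3.0, 0.0, 0.0]],
            [int(VesselLabel.ECA), int(VesselLabel.ICA)],
        )
        corr = match_stage(moving, fixed, ConditionalWeightMatrix())
        assert corr.fixed_indices[0] == 1  # the farther same-label point

    def test_unmatched_label_error_names_label(self):
        moving = LabeledPointSet([[0.0, 0.0, 0.0]], [int(VesselLabel.ICA)])
        fixed = LabeledPointSet([[1.0, 0.0, 0.0]], [int(VesselLabel.ECA)])
        with pytest.raises(UnmatchedLabelError, match="ICA"):
            match_stage(moving, fixed, ConditionalWeightMatrix())


class TestEstimateRigid:
    def test_identity_on_identical_sets(self, rng):
        s = random_labeled_set(rng, 20)
        corr = match_stage(s, s, ConditionalWeightMatrix.ones())
        t = estimate_rigid(s, corr, s)
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(t.translation, 0.0, atol=1e-12)

    def test_recovers_known_motion_exactly(self, rng):
        for _ in range(10):
            s = random_labeled_set(rng, 30)
            motion = random_rigid(rng, 90.0, 20.0)
            f = s.with_points(motion.apply(s.points))
            # perfect correspondences by construction
            corr = match_stage(f, f, ConditionalWeightMatrix.ones())
            corr.fixed_indices = np.arange(30)
            t = estimate_rigid(s, corr, f)
            np.testing.assert_allclose(t.rotation, motion.rotation, atol=1e-9)
            np.testing.assert_allclose(t.translation, motion.translation, atol=1e-9)

    def test_matches_independent_kabsch_oracle(self, rng):
        s = random_labeled_set(rng, 25)
        f = random_labeled_set(rng, 25)
        corr = match_stage(s, f, ConditionalWeightMatrix.ones())
        t = estimate_rigid(s, corr, f)
        R, tr = kabsch_oracle(s.points, f.points[corr.fixed_indices])
        np.testing.assert_allclose(t.rotation, R, atol=1e-10)
        np.testing.assert_allclose(t.translation, tr, atol=1e-10)

    def test_collinear_pairs_rejected(self):
        pts = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        s = LabeledPointSet(pts, np.zeros(5, dtype=int))
        corr = match_stage(s, s, ConditionalWeightMatrix.ones())
        with pytest.raises(DegenerateGeometryError):
            estimate_rigid(s, corr, s)


class TestRunCicp:
    def test_identity_converges_immediately(self, rng):
        s = random_labeled_set(rng, 40)
        res = run_cicp(s, s, ConditionalWeightMatrix())
        assert res.converged and res.iterations == 1
        assert res.mse_trace[-1] < 1e-12
        np.testing.assert_allclose(res.transform.rotation, np.eye(3), atol=1e-9)

    def test_equals_reference_icp_per_iteration(self, rng, fast_phantom):
        """With an all-ones weight matrix CICP is plain ICP: matches must be
        identical per iteration and transforms must agree numerically."""
        cl = extract_centerline(fast_phantom).points
        for trial in range(5):
            motion = random_rigid(rng, 10.0, 3.0)
            moving = cl.with_points(motion.apply(cl.points))
            res = run_cicp(moving, cl, ConditionalWeightMatrix.ones(), keep_history=True)
            ref = brute_force_icp(moving.points, cl.points)
            assert len(res.match_history) == len(ref["matches"])
            for got, want in zip(res.match_history, ref["matches"]):
                np.testing.assert_array_equal(got, want)
            for got, (R, t) in zip(res.transform_history, ref["transforms"]):
                np.testing.assert_allclose(got.rotation, R, atol=1e-9)
                np.testing.assert_allclose(got.translation, t, atol=1e-9)
            np.testing.assert_allclose(res.mse_trace, ref["trace"], atol=1e-9)

    @pytest.mark.parametrize("w1", [1.0, math.inf])
    def test_monotone_mse_trace(self, rng, fast_phantom, w1):
        cl = extract_centerline(fast_phantom).points
        W = ConditionalWeightMatrix(1.0, w1, math.inf)
        for trial in range(5):
            motion = random_rigid(rng, 20.0, 6.0)
            moving = cl.with_points(motion.apply(cl.points))
            res = run_cicp(moving, cl, W, max_iter=50, tol=1e-10)
            diffs = np.diff(res.mse_trace)
            assert np.all(diffs <= 1e-9)

    def test_no_branch_cross_matches_with_infinite_weight(self, rng, fast_phantom):
        cl = extract_centerline(fast_phantom).points
        motion = random_rigid(rng, 15.0, 5.0)
        moving = cl.with_points(motion.apply(cl.points))
        res = run_cicp(moving, cl, ConditionalWeightMatrix(), keep_history=True)
        for matches in res.match_history:
            pair_labels = set(zip(moving.labels.tolist(), cl.labels[matches].tolist()))
            assert (int(VesselLabel.ICA), int(VesselLabel.ECA)) not in pair_labels
            assert (int(VesselLabel.ECA), int(VesselLabel.ICA)) not in pair_labels

    def test_not_equivalent_to_per_label_icps(self):
        """The transform stage is shared: a case where per-label ICPs give
        different transforms than joint CICP."""
        rng = np.random.default_rng(3)
        # two parallel same-shape clouds with *different* offsets per label:
        # per-label ICP recovers each offset; shared CICP must compromise.
        base = rng.normal(0, 5, (30, 3))
        moving_pts = np.vstack([base, base + [20, 0, 0]])
        labels = np.array([int(VesselLabel.ICA)] * 30 + [int(VesselLabel.ECA)] * 30)
        fixed_pts = np.vstack([base + [0, 0, 1.0], base + [20, 0, -1.0]])
        moving = LabeledPointSet(moving_pts, labels)
        fixed = LabeledPointSet(fixed_pts, labels)
        W = ConditionalWeightMatrix(1.0, math.inf, math.inf)
        joint = run_cicp(moving, fixed, W)
        ica = run_cicp(moving.subset(labels == 1), fixed.subset(labels == 1), W)
        eca = run_cicp(moving.subset(labels == 2), fixed.subset(labels == 2), W)
        np.testing.assert_allclose(ica.transform.translation[2], 1.0, atol=1e-6)
        np.testing.assert_allclose(eca.transform.translation[2], -1.0, atol=1e-6)
        # the shared transform matches neither per-label solution
        assert abs(joint.transform.translation[2] - 1.0) > 0.2
        assert abs(joint.transform.translation[2] + 1.0) > 0.2

    def test_finite_surrogate_matches_infinity(self, rng, fast_phantom):
        """w2 = 10000 must behave identically to w2 = +inf on phantom data."""
        cl = extract_centerline(fast_phantom).points
        motion = random_rigid(rng, 12.0, 4.0)
        moving = cl.with_points(motion.apply(cl.points))
        res_inf = run_cicp(moving, cl, ConditionalWeightMatrix(1.0, 1.0, math.inf), keep_history=True)
        res_sur = run_cicp(moving, cl, ConditionalWeightMatrix(1.0, 1.0, 10000.0), keep_history=True)
        assert len(res_inf.match_history) == len(res_sur.match_history)
        for a, b in zip(res_inf.match_history, res_sur.match_history):
            np.testing.assert_array_equal(a, b)
        np.testing.assert_allclose(
            res_inf.transform.translation, res_sur.transform.translation, atol=1e-12
        )
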