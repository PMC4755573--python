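"""Conditional iterative closest points (CICP).

Classic ICP alternates a *match stage* (each moving point takes its nearest
fixed neighbor) and a *transform stage* (least-squares transform over all
matched pairs).  CICP changes only the match stage: the distance between a
moving point with label L_m and a fixed point with label L_f is multiplied
by a symmetric label-pair weight

        W = [[w0, w1, w1],
             [w1, w0, w2],          labels ordered (CCA, ICA, ECA)
             [w1, w2, w0]],         w1, w2 >= w0 > 0,

so same-vessel matches cost w0, CCA-to-branch matches cost w1, and
ICA-to-ECA matches cost w2 (set to +inf to forbid that anatomically
meaningless pairing).  Plain ICP is the special case with every weight 1.

The transform stage is shared across labels — CICP is *not* three per-label
ICPs — and is pluggable: a closed-form rigid solve (Kabsch/Horn SVD) for the
initialization step, or a regularized thin-plate-spline fit for the
refinement step.

Convergence: with w1 in {w0, +inf} every selected pair weight is constant
across iterations, the matched conditional distances cannot increase, and
the transform stage can never do worse than the identity, so the
mean-squared-error trace is non-increasing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .exceptions import (
    DegenerateGeometryError,
    UnmatchedLabelError,
    ValidationError,
)
from .tps import TPSTransform, farthest_point_subsample, fit_tps
from .types import LabeledPoint, LabeledPointSet, RigidTransform, VesselLabel

__all__ = [
    "ConditionalWeightMatrix",
    "CICPResult",
    "conditional_distance",
    "match_stage",
    "estimate_rigid",
    "run_cicp",
]

logger = logging.getLogger(__name__)

_INT_MAX = np.iinfo(np.int64).max


@dataclass(frozen=True)
class ConditionalWeightMatrix:
    """Symmetric 3x3 label-pair weight matrix.

    ``w0`` weights same-label pairs, ``w1`` the CCA-ICA and CCA-ECA pairs,
    ``w2`` the ICA-ECA pair (``math.inf`` forbids it; the finite surrogate
    10000 behaves identically in practice).
    """

    w0: float = 1.0
    w1: float = 1.0
    w2: float = math.inf

    def __post_init__(self) -> None:
        if not (self.w0 > 0 and math.isfinite(self.w0)):
            raise ValidationError("w0 must be positive and finite")
        if self.w1 < self.w0 or self.w2 < self.w0:
            raise ValidationError("w1 and w2 must be >= w0")

    @classmethod
    def ones(cls) -> "ConditionalWeightMatrix":
        """The all-ones matrix: CICP degenerates to plain ICP."""
        return cls(1.0, 1.0, 1.0)

    def weight(self, a: VesselLabel, b: VesselLabel) -> float:
        a, b = VesselLabel(a), VesselLabel(b)
        if a == VesselLabel.UNLABELED or b == VesselLabel.UNLABELED:
            raise ValidationError("conditional weights are undefined for UNLABELED")
        if a == b:
            return self.w0
        if VesselLabel.CCA in (a, b):
            return self.w1
        return self.w2

    def as_matrix(self) -> np.ndarray:
        m = np.array(
            [
                [self.w0, self.w1, self.w1],
                [self.w1, self.w0, self.w2],
                [self.w1, self.w2, self.w0],
            ]
        )
        return m


def conditional_distance(p: LabeledPoint, q: LabeledPoint, W: ConditionalWeightMatrix) -> float:
    """Label-weighted Euclidean distance  w_{L_p, L_q} * ||p - q||.

    An infinite weight times a zero distance is defined as 0 (coincident
    points are never penalized).
    """
    w = W.weight(p.label, q.label)
    d = float(np.linalg.norm(p.position - q.position))
    if math.isinf(w):
        return 0.0 if d == 0.0 else math.inf
    return w * d


@dataclass
class Correspondences:
    """Match-stage output: for each moving index, a fixed index and the
    conditional distance of the pair."""

    fixed_indices: np.ndarray
    distances: np.ndarray

    def __len__(self) -> int:
        return len(self.fixed_indices)


@dataclass
class CICPResult:
    """Outcome of one CICP run."""

    transform: RigidTransform | TPSTransform
    mse_trace: list[float]
    iterations: int
    converged: bool
    matches: np.ndarray
    match_history: list[np.ndarray] = field(default_factory=list)
    transform_history: list[RigidTransform | TPSTransform] = field(default_factory=list)

    @property
    def final_mse(self) -> float:
        return self.mse_trace[-1]


def _match_points(
    points: np.ndarray,
    labels: np.ndarray,
    fixed: LabeledPointSet,
    W: ConditionalWeightMatrix,
) -> Correspondences:
    """Vectorized conditional match of ``points`` against ``fixed``.

    One KD-tree per fixed label; each moving point takes the candidate
    minimizing weight * distance, ties broken by the smallest fixed index.
    """
    n = len(points)
    best_wd = np.full(n, np.inf)
    best_d = np.full(n, np.inf)
    best_idx = np.full(n, _INT_MAX, dtype=np.int64)
    wmat = W.as_matrix()
    for lf in fixed.labels_present():
        tree, gidx = fixed.tree_for(lf)
        d, j = tree.query(points)
        fixed_global = gidx[j]
        w = wmat[labels, int(lf)]
        with np.errstate(invalid="ignore"):  # inf * 0 handled explicitly below
            wd = np.where(np.isinf(w), np.where(d == 0.0, 0.0, np.inf), w * d)
        better = (wd < best_wd) | ((wd == best_wd) & np.isfinite(wd) & (fixed_global < best_idx))
        best_wd = np.where(better, wd, best_wd)
        best_d = np.where(better, d, best_d)
        best_idx = np.where(better, fixed_global, best_idx)
    bad = ~np.isfinite(best_wd)
    if np.any(bad):
        missing = sorted({VesselLabel(int(l)).name for l in np.unique(labels[bad])})
        raise UnmatchedLabelError(
            f"moving labels {missing} have no fixed candidate with finite weight"
        )
    return Correspondences(best_idx, best_wd)


def match_stage(
    moving: LabeledPointSet, fixed: LabeledPointSet, W: ConditionalWeightMatrix
) -> Correspondences:
    """Conditional match stage: argmin over fixed points of the conditional
    distance, per moving point.

    With all weights equal this reduces exactly to Euclidean nearest
    neighbor.
    """
    if moving.has_unlabeled() or fixed.has_unlabeled():
        raise ValidationError("match stage requires resolved labels on both sets")
    return _match_points(moving.points, moving.labels, fixed, W)


def estimate_rigid(
    moving: LabeledPointSet | np.ndarray,
    correspondences: Correspondences,
    fixed: LabeledPointSet,
) -> RigidTransform:
    """Least-squares rigid transform over all matched pairs jointly."""
    pts = moving.points if isinstance(moving, LabeledPointSet) else np.asarray(moving, dtype=float)
    targets = fixed.points[correspondences.fixed_indices]
    return _kabsch(pts, targets)


def _kabsch(src: np.ndarray, dst: np.ndarray, strict: bool = True) -> RigidTransform:
    """Closed-form SVD solution of the rigid least-squares problem, with
    determinant correction so reflections are excluded.

    ``strict`` rejects rank-deficient cross-covariances (collinear pairs)
    where the rotation is not unique.  The iteration loop disables it: a
    transient rank-1 match configuration (all targets collapsing onto a
    line, common under a deliberately wrong label candidate) still admits a
    minimizing rotation, and the loop recovers on the next match.
    """
    if len(src) < 3:
        raise DegenerateGeometryError("rigid estimation needs >= 3 pairs")
    mu_s = src.mean(axis=0)
    mu_d = dst.mean(axis=0)
    H = (src - mu_s).T @ (dst - mu_d)
    U, S, Vt = np.linalg.svd(H)
    if strict and S[1] <= max(S[0], 1.0) * 1e-12:
        raise DegenerateGeometryError("matched pairs are collinear; rotation undetermined")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = mu_d - R @ mu_s
    return RigidTransform(R, t)


def run_cicp(
    moving: LabeledPointSet,
    fixed: LabeledPointSet,
    W: ConditionalWeightMatrix | None = None,
    model: Literal["rigid", "tps"] = "rigid",
    max_iter: int = 50,
    tol: float = 1e-4,
    tps_lambda: float = 1.0,
    max_control_points: int = 800,
    pre_translate: bool = False,
    keep_history: bool = False,
) -> CICPResult:
    """Run CICP from the identity start.

    Alternates the conditional match stage with the chosen transform stage,
    records the mean squared error after every transform stage, and stops
    when the MSE falls below ``tol`` (mm^2), its decrease is smaller than
    ``tol``, or ``max_iter`` is reached.

    ``model="rigid"`` composes incremental Kabsch solutions; the result
    transform maps the original moving points.  ``model="tps"`` refits one
    thin-plate spline from the original moving points to the current
    correspondences each iteration (control points capped at
    ``max_control_points`` by deterministic farthest-point sampling).

    ``pre_translate`` optionally aligns the two point-set centroids before
    the first match (off by default; the method needs no manual
    pre-alignment).
    """
    if W is None:
        W = ConditionalWeightMatrix()
    if moving.has_unlabeled() or fixed.has_unlabeled():
        raise ValidationError("CICP requires resolved labels")
    if max_iter < 1:
        raise ValidationError("max_iter must be >= 1")

    cur = moving.points.copy()
    R_tot = np.eye(3)
    t_tot = np.zeros(3)
    if pre_translate and model == "rigid":
        t_tot = fixed.points.mean(axis=0) - cur.mean(axis=0)
        cur = cur + t_tot
    tps_t: TPSTransform | None = None
    trace: list[float] = []
    match_hist: list[np.ndarray] = []
    transform_hist: list[RigidTransform | TPSTransform] = []
    matches = None
    converged = False
    iterations = 0

    if model == "tps":
        sub = farthest_point_subsample(moving.points, min(max_control_points, len(moving)))

    prev_state = None
    for k in range(max_iter):
        corr = _match_points(cur, moving.labels, fixed, W)
        targets = fixed.points[corr.fixed_indices]
        if model == "rigid":
            step = _kabsch(cur, targets, strict=False)
            new_cur = cur @ step.rotation.T + step.translation
        elif model == "tps":
            new_tps = fit_tps(moving.points[sub], targets[sub], tps_lambda)
            new_cur = new_tps.apply(moving.points)
        else:
            raise ValidationError(f"unknown transform model {model!r}")
        mse = float(np.mean(np.sum((new_cur - targets) ** 2, axis=1)))
        if trace and mse > trace[-1] * (1.0 + 1e-12) + 1e-15:
            # Monotone safeguard.  The rigid stage is the exact minimizer of
            # the matched MSE and can never trip this; the regularized TPS
            # stage minimizes data + lambda * bending, so the raw MSE may
            # rise marginally when the refit trades data fit for smoothness.
            # Such a step is rejected and iteration stops at the best state.
            logger.info("CICP[%s] iter %d rejected (MSE %.6g > %.6g)",
                        model, k + 1, mse, trace[-1])
            converged = True
            break
        cur = new_cur
        if model == "rigid":
            R_tot = step.rotation @ R_tot
            t_tot = step.rotation @ t_tot + step.translation
            if keep_history:
                transform_hist.append(RigidTransform(R_tot.copy(), t_tot.copy()))
        else:
            tps_t = new_tps
            if keep_history:
                transform_hist.append(tps_t)
        trace.append(mse)
        matches = corr.fixed_indices
        if keep_history:
            match_hist.append(corr.fixed_indices.copy())
        iterations = k + 1
        logger.info("CICP[%s] iter %d: MSE %.6g mm^2", model, iterations, mse)
        if mse <= tol or (len(trace) > 1 and abs(trace[-2] - mse) < tol):
            converged = True
            break

    transform: RigidTransform | TPSTransform
    if model == "rigid":
        transform = RigidTransform(R_tot, t_tot)
    else:
        assert tps_t is not None
        transform = tps_t
    return CICPResult(
        transform=transform,
        mse_trace=trace,
        iterations=iterations,
        converged=converged,
        matches=matches,
        match_history=match_hist,
        transform_history=transform_hist,
    )
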