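"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive: O(N^2) scans, dense rasterization,
plain least squares.  None of it shares code with the package internals.
"""

from __future__ import annotations

import math

import numpy as np


def rasterized_centroid(vertices: np.ndarray, pitch: float) -> np.ndarray:
    """Area centroid as the mean of a dense grid of points inside the polygon."""
    from matplotlib.path import Path

    v = np.asarray(vertices, dtype=float)
    lo = v.min(axis=0) - pitch
    hi = v.max(axis=0) + pitch
    xs = np.arange(lo[0], hi[0] + pitch, pitch)
    ys = np.arange(lo[1], hi[1] + pitch, pitch)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    inside = Path(v).contains_points(pts)
    return pts[inside].mean(axis=0)


def brute_force_match(
    moving_pts: np.ndarray,
    moving_labels: np.ndarray,
    fixed_pts: np.ndarray,
    fixed_labels: np.ndarray,
    weight_matrix: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Exhaustive conditional-distance argmin; smallest fixed index wins ties.

    ``weight_matrix`` is the 3x3 label-pair weight lookup; an infinite weight
    with zero distance counts as conditional distance 0.
    """
    nm = len(moving_pts)
    idx = np.empty(nm, dtype=int)
    dist = np.empty(nm)
    for i in range(nm):
        best = (math.inf, -1)
        for j in range(len(fixed_pts)):
            w = weight_matrix[int(moving_labels[i]), int(fixed_labels[j])]
            d = float(np.linalg.norm(moving_pts[i] - fixed_pts[j]))
            wd = (0.0 if d == 0.0 else math.inf) if math.isinf(w) else w * d
            if wd < best[0]:
                best = (wd, j)
        if best[1] < 0:
            raise AssertionError("oracle found no finite-weight candidate")
        idx[i], dist[i] = best[1], best[0]
    return idx, dist


def kabsch_oracle(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Textbook rigid least squares via SVD (independent implementation)."""
    cs, cd = src.mean(0), dst.mean(0)
    U, _, Vt = np.linalg.svd((src - cs).T @ (dst - cd))
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    return R, cd - R @ cs


def brute_force_icp(
    moving: np.ndarray, fixed: np.ndarray, max_iter: int = 50, tol: float = 1e-4
) -> dict:
    """Reference plain ICP: exhaustive Euclidean nearest neighbor + Kabsch.

    Returns per-iteration matches, cumulative transforms and the MSE trace.
    """
    cur = moving.copy()
    R_tot, t_tot = np.eye(3), np.zeros(3)
    matches, transforms, trace = [], [], []
    for _ in range(max_iter):
        d2 = ((cur[:, None, :] - fixed[None, :, :]) ** 2).sum(axis=2)
        idx = np.argmin(d2, axis=1)
        targets = fixed[idx]
        R, t = kabsch_oracle(cur, targets)
        cur = cur @ R.T + t
        R_tot, t_tot = R @ R_tot, R @ t_tot + t
        matches.append(idx)
        transforms.append((R_tot.copy(), t_tot.copy()))
        mse = float(np.mean(np.sum((cur - targets) ** 2, axis=1)))
        trace.append(mse)
        if mse <= tol or (len(trace) > 1 and abs(trace[-2] - mse) < tol):
            break
    return {"matches": matches, "transforms": transforms, "trace": trace}


def brute_force_labeled_distances(
    moving_pts: np.ndarray,
    moving_labels: np.ndarray,
    fixed_pts: np.ndarray,
    fixed_labels: np.ndarray,
    allowed_pairs: set[frozenset],
) -> np.ndarray:
    """Exhaustive nearest compatible-label distances (double loop)."""
    out = np.empty(len(moving_pts))
    for i in range(len(moving_pts)):
        best = math.inf
        for j in range(len(fixed_pts)):
            if frozenset((int(moving_labels[i]), int(fixed_labels[j]))) not in allowed_pairs:
                continue
            best = min(best, float(np.linalg.norm(moving_pts[i] - fixed_pts[j])))
        out[i] = best
    return out


def best_fit_affine(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares affine map Y ~= X A + b via lstsq."""
    Q = np.column_stack([np.ones(len(X)), X])
    sol, *_ = np.linalg.lstsq(Q, Y, rcond=None)
    return sol[1:], sol[0]
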