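"""3D thin-plate-spline (TPS) transform.

The TPS maps a point x through an affine part plus a radial kernel warp
anchored at the N control points m_j:

    f(x) = D . [1, x]^T  +  P . phi(x),      phi_j(x) = ||x - m_j||_2

with D a 4x4 homogeneous affine matrix and P a 4xN warp-coefficient matrix
(first rows of D and P reproduce the homogeneous 1).  The fit minimizes a
squared data term plus lambda times the 3D bending energy; the minimizer is
the solution of one bordered linear system

    [ K + lambda I   Q ] [ w ]   [ y ]
    [ Q^T            0 ] [ a ] = [ 0 ]

with K_ij = ||m_i - m_j||, Q = [1 | m] and side conditions Q^T w = 0 that
strip the affine component out of the kernel part.  The biharmonic kernel
r is conditionally negative definite, so on the constrained subspace the
bending energy is the nonnegative quadratic form -w^T K w.

Control-point coordinates are centered and scaled to unit RMS radius before
solving (kernel systems on mm-scale anatomy are ill-conditioned); the
normalization is folded back into the stored D and P so the public transform
acts directly in mm.  The regularizer is rescaled (lambda / s) so that
lambda keeps its meaning against mm-scale residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import LinAlgError, solve
from scipy.spatial.distance import cdist

from .exceptions import SingularSystemError, ValidationError

__all__ = [
    "TPSTransform",
    "tps_kernel",
    "fit_tps",
    "apply_tps",
    "tps_objective",
    "farthest_point_subsample",
]


def tps_kernel(p: np.ndarray, q: np.ndarray) -> float:
    """Radial kernel value ||p - q||_2 (3D biharmonic spline)."""
    return float(np.linalg.norm(np.asarray(p, dtype=float) - np.asarray(q, dtype=float)))


@dataclass(frozen=True)
class TPSTransform:
    """Fitted thin-plate-spline transform in homogeneous form.

    Attributes
    ----------
    control_points
        (N, 3) control points (the moving points used in fitting), mm.
    affine
        4x4 matrix D acting on [1, x, y, z]^T; first row is [1, 0, 0, 0].
    warp
        4xN coefficient matrix P; first row is zero and the remaining rows
        satisfy the side conditions (orthogonal to [1 | control_points]).
    lambda_reg
        Regularization constant used in the fit.
    """

    control_points: np.ndarray
    affine: np.ndarray
    warp: np.ndarray
    lambda_reg: float

    def __post_init__(self) -> None:
        cp = np.asarray(self.control_points, dtype=float)
        D = np.asarray(self.affine, dtype=float)
        P = np.asarray(self.warp, dtype=float)
        if cp.ndim != 2 or cp.shape[1] != 3:
            raise ValidationError("control_points must be (N, 3)")
        if D.shape != (4, 4) or P.shape != (4, cp.shape[0]):
            raise ValidationError("affine must be 4x4 and warp 4xN")
        if self.lambda_reg < 0:
            raise ValidationError("lambda_reg must be >= 0")
        object.__setattr__(self, "control_points", cp)
        object.__setattr__(self, "affine", D)
        object.__setattr__(self, "warp", P)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return apply_tps(self, points)

    def side_condition_residual(self) -> float:
        """Max violation of the orthogonality side conditions."""
        W = self.warp[1:]  # (3, N)
        Q = np.column_stack([np.ones(len(self.control_points)), self.control_points])
        return float(np.max(np.abs(W @ Q)))

    def bending_energy(self) -> float:
        """Bending quadratic form  -sum_d w_d^T K w_d  (>= 0 up to fp noise)."""
        K = cdist(self.control_points, self.control_points)
        W = self.warp[1:]
        return float(-np.einsum("dn,nm,dm->", W, K, W))

    def to_dict(self) -> dict:
        return {
            "control_points": self.control_points.tolist(),
            "affine": self.affine.tolist(),
            "warp": self.warp.tolist(),
            "lambda_reg": self.lambda_reg,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TPSTransform":
        return cls(
            np.asarray(d["control_points"], dtype=float),
            np.asarray(d["affine"], dtype=float),
            np.asarray(d["warp"], dtype=float),
            float(d["lambda_reg"]),
        )


def fit_tps(moving: np.ndarray, targets: np.ndarray, lambda_reg: float = 1.0) -> TPSTransform:
    """Fit the regularized TPS mapping ``moving[i] -> targets[i]``.

    At ``lambda_reg = 0`` with distinct, non-coplanar moving points the fit
    interpolates the targets exactly; for affine target fields the warp
    vanishes at every lambda (the affine family has zero bending energy).
    """
    X = np.asarray(moving, dtype=float)
    Y = np.asarray(targets, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3 or Y.shape != X.shape:
        raise ValidationError("moving and targets must be matching (N, 3) arrays")
    n = X.shape[0]
    if n < 5:
        raise ValidationError("TPS fit needs at least 5 point pairs")
    if lambda_reg < 0:
        raise ValidationError("lambda_reg must be >= 0")

    center = X.mean(axis=0)
    scale = float(np.sqrt(np.mean(np.sum((X - center) ** 2, axis=1))))
    if scale <= 0:
        raise SingularSystemError("all control points coincide")
    Xn = (X - center) / scale
    Yn = (Y - center) / scale

    Q = np.column_stack([np.ones(n), Xn])
    if np.linalg.matrix_rank(Q, tol=1e-9) < 4:
        raise SingularSystemError("control points are coplanar or collinear")

    # Internally the system uses the conditionally positive-definite
    # orientation -r of the distance kernel so that K + lambda I is the
    # classical smoothing system; the stored warp P is re-expressed for the
    # public +r kernel by flipping its sign.
    K = -cdist(Xn, Xn)
    lam_n = lambda_reg / scale
    A = np.zeros((n + 4, n + 4))
    A[:n, :n] = K + lam_n * np.eye(n)
    A[:n, n:] = Q
    A[n:, :n] = Q.T
    rhs = np.zeros((n + 4, 3))
    rhs[:n] = Yn
    try:
        sol = solve(A, rhs)
    except LinAlgError as e:
        raise SingularSystemError(f"TPS system is singular: {e}") from e
    if not np.all(np.isfinite(sol)):
        raise SingularSystemError("TPS system produced non-finite coefficients")
    Wn = -sol[:n]       # (N, 3) coefficients for the public +r kernel
    An = sol[n:]        # (4, 3): row 0 constant, rows 1:4 linear map

    # Fold the normalization back into mm-frame D and P.  The kernel scales
    # linearly, so the warp coefficients transfer unchanged:
    #   y = c + s*(a0 + (x-c)/s @ A_lin) + sum_j w_j ||x - x_j|| / s * s
    A_lin = An[1:]                      # (3, 3), row-vector convention
    b = center + scale * An[0] - center @ A_lin
    D = np.zeros((4, 4))
    D[0, 0] = 1.0
    D[1:, 0] = b
    D[1:, 1:] = A_lin.T
    P = np.zeros((4, n))
    P[1:] = Wn.T
    return TPSTransform(X.copy(), D, P, float(lambda_reg))


def apply_tps(t: TPSTransform, points: np.ndarray) -> np.ndarray:
    """Evaluate the transform at arbitrary points (smooth extension)."""
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    lin = pts @ t.affine[1:, 1:].T + t.affine[1:, 0]
    k = cdist(pts, t.control_points)
    out = lin + k @ t.warp[1:].T
    return out[0] if single else out


def tps_objective(t: TPSTransform, moving: np.ndarray, targets: np.ndarray) -> float:
    """Regularized objective: data term + lambda_reg * bending energy.

    This is the quantity (up to the universal kernel constant) that
    :func:`fit_tps` minimizes over the TPS family anchored at the same
    control points.
    """
    res = apply_tps(t, moving) - np.asarray(targets, dtype=float)
    return float(np.sum(res**2) + t.lambda_reg * t.bending_energy())


def farthest_point_subsample(points: np.ndarray, k: int, start: int = 0) -> np.ndarray:
    """Deterministic farthest-point sampling; returns sorted indices.

    Starts from ``start`` and greedily adds the point farthest from the
    current set.  Used to cap the TPS control-point count: a dense system on
    thousands of surface samples is needlessly expensive and the spacing-
    maximizing subset preserves the deformation field.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if k >= n:
        return np.arange(n)
    chosen = np.empty(k, dtype=int)
    chosen[0] = start
    dist = np.linalg.norm(pts - pts[start], axis=1)
    for i in range(1, k):
        nxt = int(np.argmax(dist))
        chosen[i] = nxt
        dist = np.minimum(dist, np.linalg.norm(pts - pts[nxt], axis=1))
    return np.sort(chosen)
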