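"""Core data model: vessel labels, per-slice contours, contour stacks,
labeled 3D point sets and rigid transforms.

Everything is in millimetres.  A :class:`ContourStack` is the package's only
raw input: a stack of closed 2D lumen polygons, each living in a plane of
constant z (the slice-stacking axis) and carrying a vessel label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .exceptions import ValidationError

__all__ = [
    "VesselLabel",
    "Contour2D",
    "ContourStack",
    "LabeledPoint",
    "LabeledPointSet",
    "RigidTransform",
    "signed_area",
]


class VesselLabel(IntEnum):
    """Vessel category of a contour or point.

    CCA / ICA / ECA are the common, internal and external carotid artery.
    UNLABELED is legal on raw input only; every registration entry point
    requires resolved labels (see :mod:`tacicp.labeling`).
    """

    CCA = 0
    ICA = 1
    ECA = 2
    UNLABELED = 3

    @classmethod
    def from_name(cls, name: str) -> "VesselLabel":
        try:
            return cls[name.upper()]
        except KeyError:
            raise ValidationError(f"unknown vessel label {name!r}") from None


#: the three real vessel labels (everything except UNLABELED)
REAL_LABELS = (VesselLabel.CCA, VesselLabel.ICA, VesselLabel.ECA)


def signed_area(vertices: np.ndarray) -> float:
    """Signed area of a closed polygon given its N vertices (shoelace).

    The polygon is closed implicitly: the edge from the last vertex back to
    the first is included.  Positive for counter-clockwise vertex order.
    """
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    return 0.5 * float(np.sum(x * yn - xn * y))


@dataclass(frozen=True)
class Contour2D:
    """One closed per-slice lumen polygon.

    Parameters
    ----------
    z_mm
        Slice position along the stacking axis.
    vertices
        Ordered (N, 2) array of planar vertices in mm, N >= 3.  The polygon
        is closed implicitly; do not repeat the first vertex at the end.
    label
        Vessel category.
    """

    z_mm: float
    vertices: np.ndarray
    label: VesselLabel = VesselLabel.UNLABELED

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValidationError(
                f"contour vertices must be (N, 2), got shape {v.shape}"
            )
        if v.shape[0] < 3:
            raise ValidationError(f"contour needs >= 3 vertices, got {v.shape[0]}")
        if not np.all(np.isfinite(v)):
            raise ValidationError("contour vertices must be finite")
        if not math.isfinite(self.z_mm):
            raise ValidationError("contour z_mm must be finite")
        if abs(signed_area(v)) < 1e-12:
            raise ValidationError("degenerate contour: signed area is zero")
        v.setflags(write=False)
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "z_mm", float(self.z_mm))
        object.__setattr__(self, "label", VesselLabel(self.label))

    @property
    def n_vertices(self) -> int:
        return int(self.vertices.shape[0])

    def with_label(self, label: VesselLabel) -> "Contour2D":
        return Contour2D(self.z_mm, np.array(self.vertices), label)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Contour2D):
            return NotImplemented
        return (
            self.z_mm == other.z_mm
            and self.label == other.label
            and self.vertices.shape == other.vertices.shape
            and bool(np.all(self.vertices == other.vertices))
        )


@dataclass
class ContourStack:
    """A stack of labeled per-slice contours from one image.

    Contours are kept sorted ascending by ``z_mm`` (stable within a slice).
    A slice holds between 1 and 3 contours and never two contours with the
    same non-UNLABELED label.
    """

    contours: list[Contour2D]
    slice_spacing_mm: float
    source_tag: str = ""

    def __post_init__(self) -> None:
        if not self.contours:
            raise ValidationError("contour stack must be nonempty")
        if not (self.slice_spacing_mm > 0 and math.isfinite(self.slice_spacing_mm)):
            raise ValidationError("slice_spacing_mm must be positive and finite")
        self.contours = sorted(self.contours, key=lambda c: c.z_mm)
        for z, group in self.slices():
            if len(group) > 3:
                raise ValidationError(f"slice z={z}: more than 3 contours")
            labels = [c.label for c in group if c.label != VesselLabel.UNLABELED]
            if len(labels) != len(set(labels)):
                raise ValidationError(
                    f"slice z={z}: duplicate label among {sorted(l.name for l in labels)}"
                )

    def slices(self) -> list[tuple[float, list[Contour2D]]]:
        """Group contours by exact z, ascending."""
        out: list[tuple[float, list[Contour2D]]] = []
        for c in self.contours:
            if out and out[-1][0] == c.z_mm:
                out[-1][1].append(c)
            else:
                out.append((c.z_mm, [c]))
        return out

    @property
    def z_values(self) -> np.ndarray:
        return np.array([z for z, _ in self.slices()])

    def is_fully_labeled(self) -> bool:
        return all(c.label != VesselLabel.UNLABELED for c in self.contours)

    def labels_present(self) -> set[VesselLabel]:
        return {c.label for c in self.contours}

    def contours_for(self, label: VesselLabel) -> list[Contour2D]:
        return [c for c in self.contours if c.label == label]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ContourStack):
            return NotImplemented
        return (
            self.slice_spacing_mm == other.slice_spacing_mm
            and self.source_tag == other.source_tag
            and len(self.contours) == len(other.contours)
            and all(a == b for a, b in zip(self.contours, other.contours))
        )


@dataclass(frozen=True)
class LabeledPoint:
    """A single 3D point in mm with a vessel label."""

    position: np.ndarray
    label: VesselLabel

    def __post_init__(self) -> None:
        p = np.asarray(self.position, dtype=float).reshape(3)
        if not np.all(np.isfinite(p)):
            raise ValidationError("point position must be finite")
        object.__setattr__(self, "position", p)
        object.__setattr__(self, "label", VesselLabel(self.label))


class LabeledPointSet:
    """A set of labeled 3D points — the unit both CICP steps operate on.

    Parameters
    ----------
    points
        (N, 3) float array, mm.
    labels
        (N,) array of :class:`VesselLabel` values.
    role
        ``"centerline"`` or ``"surface"``.
    """

    def __init__(self, points: np.ndarray, labels: np.ndarray, role: str = "surface"):
        pts = np.ascontiguousarray(points, dtype=float)
        labs = np.asarray(labels, dtype=np.int8)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValidationError(f"points must be (N, 3), got {pts.shape}")
        if pts.shape[0] == 0:
            raise ValidationError("point set must be nonempty")
        if labs.shape != (pts.shape[0],):
            raise ValidationError("labels must be one per point")
        if not np.all(np.isfinite(pts)):
            raise ValidationError("points must be finite")
        if role not in ("centerline", "surface"):
            raise ValidationError(f"unknown role {role!r}")
        valid = {int(l) for l in VesselLabel}
        if not set(np.unique(labs)).issubset(valid):
            raise ValidationError("labels contain values outside VesselLabel")
        self.points = pts
        self.labels = labs
        self.role = role
        self._trees: dict[int, tuple[cKDTree, np.ndarray]] = {}

    def __len__(self) -> int:
        return int(self.points.shape[0])

    def label_counts(self) -> dict[VesselLabel, int]:
        labs, counts = np.unique(self.labels, return_counts=True)
        return {VesselLabel(int(l)): int(c) for l, c in zip(labs, counts)}

    def labels_present(self) -> list[VesselLabel]:
        return [VesselLabel(int(l)) for l in np.unique(self.labels)]

    def has_unlabeled(self) -> bool:
        return bool(np.any(self.labels == int(VesselLabel.UNLABELED)))

    def subset(self, mask: np.ndarray) -> "LabeledPointSet":
        return LabeledPointSet(self.points[mask], self.labels[mask], self.role)

    def tree_for(self, label: VesselLabel) -> tuple[cKDTree, np.ndarray]:
        """KD-tree over the points of one label plus their global indices.

        Cached; callers must not mutate ``points`` in place.
        """
        key = int(label)
        if key not in self._trees:
            idx = np.flatnonzero(self.labels == key)
            if idx.size == 0:
                raise ValidationError(f"no points with label {VesselLabel(key).name}")
            self._trees[key] = (cKDTree(self.points[idx]), idx)
        return self._trees[key]

    def with_points(self, points: np.ndarray) -> "LabeledPointSet":
        """Same labels/role, new coordinates (e.g. after a transform)."""
        return LabeledPointSet(points, self.labels, self.role)

    def iter_points(self) -> Iterable[LabeledPoint]:
        for p, l in zip(self.points, self.labels):
            yield LabeledPoint(p, VesselLabel(int(l)))


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform ``x -> R @ x + t`` (rotation + translation)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.all(np.isfinite(R)) or not np.all(np.isfinite(t)):
            raise ValidationError("rigid transform must be finite")
        if np.max(np.abs(R @ R.T - np.eye(3))) > 1e-9:
            raise ValidationError("rotation must be orthonormal (R R^T = I)")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValidationError("rotation must be proper (det = +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_rotvec(cls, rotvec_deg: Sequence[float], translation: Sequence[float]) -> "RigidTransform":
        """Build from an axis-angle rotation vector in degrees."""
        R = Rotation.from_rotvec(np.asarray(rotvec_deg, dtype=float), degrees=True)
        return cls(R.as_matrix(), np.asarray(translation, dtype=float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        pts = np.atleast_2d(pts)
        out = pts @ self.rotation.T + self.translation
        return out[0] if single else out

    def compose(self, inner: "RigidTransform") -> "RigidTransform":
        """Return self ∘ inner (apply ``inner`` first)."""
        return RigidTransform(
            self.rotation @ inner.rotation,
            self.rotation @ inner.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation in degrees."""
        return float(
            np.degrees(np.linalg.norm(Rotation.from_matrix(self.rotation).as_rotvec()))
        )

    def to_dict(self) -> dict:
        q = Rotation.from_matrix(self.rotation).as_quat()  # (x, y, z, w)
        return {"quaternion_xyzw": q.tolist(), "translation_mm": self.translation.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        R = Rotation.from_quat(np.asarray(d["quaternion_xyzw"], dtype=float))
        return cls(R.as_matrix(), np.asarray(d["translation_mm"], dtype=float))
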