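"""Labeled surface-distance evaluation metrics.

* LMSD — labeled mean surface distance: for every point on the transformed
  moving surface, the distance to the nearest fixed-surface point with a
  *compatible* label, averaged.  Asymmetric (moving -> fixed), exactly as
  the defining formula is written; a symmetric average is available behind
  a flag.
* LMAXD — the same construction with the maximum instead of the mean
  (reveals imbalanced local errors).
* RSR — registration success rate over a batch: the fraction of cases with
  LMSD strictly below a threshold (1.5 mm by default).

Label compatibility encodes the bifurcation tolerance: same-label pairs and
CCA-ICA / CCA-ECA pairs are allowed (labels near the bifurcation are
uncertain), while ICA-ECA pairs never are.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .exceptions import UnmatchedLabelError, ValidationError
from .types import LabeledPointSet, VesselLabel

__all__ = [
    "LabelCompatibility",
    "MetricReport",
    "lmsd",
    "lmaxd",
    "rsr",
    "lmsd_by_position",
    "labeled_nn_distances",
]


def _pair(a: VesselLabel, b: VesselLabel) -> frozenset:
    return frozenset((VesselLabel(a), VesselLabel(b)))


@dataclass(frozen=True)
class LabelCompatibility:
    """Set of unordered label pairs allowed to correspond in evaluation."""

    allowed_pairs: frozenset = field(
        default_factory=lambda: frozenset(
            {
                _pair(VesselLabel.CCA, VesselLabel.CCA),
                _pair(VesselLabel.ICA, VesselLabel.ICA),
                _pair(VesselLabel.ECA, VesselLabel.ECA),
                _pair(VesselLabel.CCA, VesselLabel.ICA),
                _pair(VesselLabel.CCA, VesselLabel.ECA),
            }
        )
    )

    @classmethod
    def all_pairs(cls) -> "LabelCompatibility":
        """Every label pair allowed — plain unlabeled surface distance."""
        labs = (VesselLabel.CCA, VesselLabel.ICA, VesselLabel.ECA)
        return cls(frozenset(_pair(a, b) for a in labs for b in labs))

    def allows(self, a: VesselLabel, b: VesselLabel) -> bool:
        return _pair(a, b) in self.allowed_pairs

    def compatible_with(self, label: VesselLabel) -> list[VesselLabel]:
        labs = (VesselLabel.CCA, VesselLabel.ICA, VesselLabel.ECA)
        return [l for l in labs if self.allows(label, l)]


@dataclass
class MetricReport:
    """Serializable summary of one evaluation."""

    lmsd_mm: float
    lmaxd_mm: float
    n_points: int
    per_slice_lmsd: list[tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.lmsd_mm <= self.lmaxd_mm + 1e-12):
            raise ValidationError("requires 0 <= lmsd <= lmaxd")

    def to_dict(self) -> dict:
        d = {"lmsd_mm": self.lmsd_mm, "lmaxd_mm": self.lmaxd_mm, "n_points": self.n_points}
        if self.per_slice_lmsd is not None:
            d["per_slice_lmsd"] = [[z, v] for z, v in self.per_slice_lmsd]
        return d


def labeled_nn_distances(
    moving_surface: LabeledPointSet,
    fixed_surface: LabeledPointSet,
    compat: LabelCompatibility | None = None,
) -> np.ndarray:
    """Per-moving-point distance to the nearest compatible fixed point."""
    if compat is None:
        compat = LabelCompatibility()
    if moving_surface.has_unlabeled() or fixed_surface.has_unlabeled():
        raise ValidationError("metrics require resolved labels")
    dists = np.full(len(moving_surface), np.inf)
    present = set(fixed_surface.labels_present())
    for lm in moving_surface.labels_present():
        mask = moving_surface.labels == int(lm)
        candidates = [l for l in compat.compatible_with(lm) if l in present]
        if not candidates:
            raise UnmatchedLabelError(
                f"no fixed point with a label compatible with {lm.name}"
            )
        best = np.full(int(mask.sum()), np.inf)
        for lf in candidates:
            tree, _ = fixed_surface.tree_for(lf)
            d, _ = tree.query(moving_surface.points[mask])
            best = np.minimum(best, d)
        dists[mask] = best
    return dists


def lmsd(
    moving_surface: LabeledPointSet,
    fixed_surface: LabeledPointSet,
    compat: LabelCompatibility | None = None,
    symmetric: bool = False,
) -> float:
    """Labeled mean surface distance in mm (moving -> fixed).

    With ``symmetric=True`` the average of both directions is returned.
    """
    fwd = float(np.mean(labeled_nn_distances(moving_surface, fixed_surface, compat)))
    if not symmetric:
        return fwd
    bwd = float(np.mean(labeled_nn_distances(fixed_surface, moving_surface, compat)))
    return 0.5 * (fwd + bwd)


def lmaxd(
    moving_surface: LabeledPointSet,
    fixed_surface: LabeledPointSet,
    compat: LabelCompatibility | None = None,
    symmetric: bool = False,
) -> float:
    """Labeled maximum surface distance in mm (moving -> fixed)."""
    fwd = float(np.max(labeled_nn_distances(moving_surface, fixed_surface, compat)))
    if not symmetric:
        return fwd
    bwd = float(np.max(labeled_nn_distances(fixed_surface, moving_surface, compat)))
    return max(fwd, bwd)


def rsr(lmsd_values: Sequence[float], threshold_mm: float = 1.5) -> float:
    """Registration success rate: fraction of values strictly below the
    threshold (a value exactly at the threshold counts as failure)."""
    vals = np.asarray(list(lmsd_values), dtype=float)
    if vals.size == 0:
        raise ValidationError("rsr needs a nonempty list of LMSD values")
    if not threshold_mm > 0:
        raise ValidationError("threshold must be positive")
    return float(np.mean(vals < threshold_mm))


def lmsd_by_position(
    moving_surface: LabeledPointSet,
    fixed_surface: LabeledPointSet,
    compat: LabelCompatibility | None = None,
    bifurcation_z: float = 0.0,
    bin_width_mm: float = 1.0,
) -> list[tuple[float, float]]:
    """LMSD per z-bin of the moving surface, keyed by z - bifurcation_z.

    Bins are ``bin_width_mm`` wide and centred on integer multiples of the
    width; empty bins are omitted.  ``bifurcation_z`` is typically the z of
    the lowest slice containing two contours.
    """
    if bin_width_mm <= 0:
        raise ValidationError("bin_width_mm must be positive")
    d = labeled_nn_distances(moving_surface, fixed_surface, compat)
    rel = moving_surface.points[:, 2] - bifurcation_z
    bins = np.round(rel / bin_width_mm).astype(int)
    out = []
    for b in np.unique(bins):
        mask = bins == b
        out.append((float(b * bin_width_mm), float(np.mean(d[mask]))))
    return out


def bifurcation_z_of(stack) -> float:
    """z of the lowest slice containing two contours (the bifurcation
    slice); raises if no slice has two contours."""
    for z, group in stack.slices():
        if len(group) == 2:
            return float(z)
    raise ValidationError("stack has no two-contour slice (no bifurcation)")
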