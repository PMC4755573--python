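"""Automatic vessel-label assignment for unlabeled contour stacks.

The carotid geometry fixes most labels for free: every slice with a single
contour is CCA (below the bifurcation).  Slices with two contours are
ambiguous — the pair could be (ECA, ICA) or (ICA, ECA).  Because the
bifurcation is anatomically asymmetric, the wrong assignment produces a
visibly larger registration error, so both candidate configurations are
registered rigidly against the labeled fixed stack and the one with the
smaller labeled mean surface distance (LMSD) wins.  The LMSD of each
candidate is computed against the candidate's own labels, i.e. the same
labels used during that registration.

On (near-)symmetric anatomies the two scores are statistically
indistinguishable; that is the method's documented failure mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

from .cicp import CICPResult, run_cicp
from .config import TACICPConfig
from .exceptions import ValidationError
from .features import build_surface_samples, extract_centerline, polygon_centroid
from .metrics import lmsd
from .types import ContourStack, VesselLabel

__all__ = ["LabelConfiguration", "assign_candidate_labels", "select_label_configuration"]

logger = logging.getLogger(__name__)

Ordering = Literal["ECA_ICA", "ICA_ECA"]


@dataclass
class LabelConfiguration:
    """One candidate labeling plus its selection score."""

    ordering: Ordering
    labeled_stack: ContourStack
    selection_score: float
    chosen: bool
    rigid_result: CICPResult | None = None


def assign_candidate_labels(stack: ContourStack, ordering: Ordering) -> ContourStack:
    """Assign labels under one candidate ECA/ICA ordering.

    Single-contour slices become CCA.  In a two-contour slice the contours
    are put in a deterministic in-slice order — ascending centroid x, ties
    by centroid y — and receive (ECA, ICA) or (ICA, ECA) per ``ordering``.
    Pre-existing labels are ignored.
    """
    if ordering not in ("ECA_ICA", "ICA_ECA"):
        raise ValidationError(f"unknown ordering {ordering!r}")
    first, second = (
        (VesselLabel.ECA, VesselLabel.ICA)
        if ordering == "ECA_ICA"
        else (VesselLabel.ICA, VesselLabel.ECA)
    )
    relabeled = []
    for z, group in stack.slices():
        if len(group) == 1:
            relabeled.append(group[0].with_label(VesselLabel.CCA))
        elif len(group) == 2:
            ordered = sorted(group, key=lambda c: tuple(polygon_centroid(c)))
            relabeled.append(ordered[0].with_label(first))
            relabeled.append(ordered[1].with_label(second))
        else:
            raise ValidationError(
                f"slice z={z}: auto-labeling needs 1 or 2 contours, got {len(group)}"
            )
    return ContourStack(relabeled, stack.slice_spacing_mm, stack.source_tag)


def select_label_configuration(
    moving_stack: ContourStack,
    fixed_stack: ContourStack,
    cfg: TACICPConfig | None = None,
) -> tuple[LabelConfiguration, LabelConfiguration]:
    """Try both candidate labelings of the moving stack, register each
    rigidly against the (labeled) fixed stack, and choose by LMSD.

    Returns (chosen, rejected).  A tie chooses ECA_ICA with a warning.
    """
    if cfg is None:
        cfg = TACICPConfig()
    if not fixed_stack.is_fully_labeled():
        raise ValidationError("fixed stack must be fully labeled")

    W = cfg.weights()
    fixed_centerline = extract_centerline(fixed_stack, cfg.centerline_interval_mm)
    fixed_surface = build_surface_samples(fixed_stack, cfg.surface_target_points)

    candidates: list[LabelConfiguration] = []
    for ordering in ("ECA_ICA", "ICA_ECA"):
        cand_stack = assign_candidate_labels(moving_stack, ordering)
        centerline = extract_centerline(cand_stack, cfg.centerline_interval_mm)
        result = run_cicp(
            centerline.points,
            fixed_centerline.points,
            W,
            model="rigid",
            max_iter=cfg.rigid_max_iter,
            tol=cfg.tol_mm2,
            pre_translate=cfg.pre_translate,
        )
        surface = build_surface_samples(cand_stack, cfg.surface_target_points)
        moved = surface.points.with_points(result.transform.apply(surface.points.points))
        score = lmsd(moved, fixed_surface.points)
        logger.info("label candidate %s: rigid LMSD %.4f mm", ordering, score)
        candidates.append(LabelConfiguration(ordering, cand_stack, score, False, result))

    a, b = candidates
    if a.selection_score == b.selection_score:
        logger.warning("label configuration scores tied; choosing ECA_ICA")
        chosen, rejected = a, b
    elif a.selection_score < b.selection_score:
        chosen, rejected = a, b
    else:
        chosen, rejected = b, a
    chosen.chosen = True
    return chosen, rejected
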