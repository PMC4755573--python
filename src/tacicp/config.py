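"""Pipeline configuration."""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, fields

from .cicp import ConditionalWeightMatrix
from .exceptions import ValidationError

__all__ = ["TACICPConfig"]


@dataclass
class TACICPConfig:
    """All tunables of the two-step pipeline, with their defaults.

    Weights: w0 = 1 (same vessel), w1 = 1 (CCA to branch; labels near the
    bifurcation are genuinely ambiguous, and w1 = 1 also guarantees the
    monotone-MSE convergence argument), w2 = +inf (ICA-ECA matches are
    anatomically meaningless).  The TPS regularization lambda defaults to 1.
    Distances in mm, tolerances in mm^2.
    """

    w0: float = 1.0
    w1: float = 1.0
    w2: float = math.inf
    lambda_reg: float = 1.0
    centerline_interval_mm: float = 1.0
    surface_target_points: int = 3500
    rigid_max_iter: int = 50
    nonrigid_max_iter: int = 50
    tol_mm2: float = 1e-4
    rsr_threshold_mm: float = 1.5
    max_control_points: int = 800
    pre_translate: bool = False
    autolabel: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("lambda_reg",):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in (
            "centerline_interval_mm",
            "surface_target_points",
            "rigid_max_iter",
            "nonrigid_max_iter",
            "tol_mm2",
            "rsr_threshold_mm",
            "max_control_points",
        ):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")
        # weight constraints are validated by ConditionalWeightMatrix
        self.weights()

    def weights(self) -> ConditionalWeightMatrix:
        return ConditionalWeightMatrix(self.w0, self.w1, self.w2)

    def to_dict(self) -> dict:
        d = asdict(self)
        if math.isinf(d["w2"]):
            d["w2"] = "inf"
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TACICPConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if d.get("w2") == "inf":
            d["w2"] = math.inf
        return cls(**d)
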