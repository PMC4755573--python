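"""Synthetic carotid-bifurcation phantoms.

A phantom is a Y-shaped arrangement of circular tubes sampled as per-slice
contours: a common carotid (CCA) tube along the z-axis up to the bifurcation
height, then an internal (ICA) and an external (ECA) branch as straight
oblique tubes whose constant-z cross-sections are ellipses (semi-axis
r / cos(theta) along the tilt direction).  Branch axes are offset laterally
just enough that the two contours never overlap in a slice, keeping every
slice a valid labeled input.  Branches are straight by construction so the
ground truth stays closed form; bending is injected only through
:class:`DeformationSpec`.

A registration case deforms the phantom by, in order: a smooth sinusoidal
bend, a twist about z (linear in z), a rigid motion, and finally optional
zero-mean Gaussian noise on the in-plane vertex coordinates — the noise
model used to probe robustness to segmentation error.  Deformed tubes are
re-expressed as per-slice contours by re-slicing each vertex track at the
original z positions (linear interpolation), and the exact noiseless
point-to-point displacement map is returned for ground-truth scoring.

Everything is deterministic given the seeds.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace
from typing import Callable

import numpy as np

from .exceptions import ValidationError
from .types import Contour2D, ContourStack, RigidTransform, VesselLabel

__all__ = [
    "PhantomSpec",
    "DeformationSpec",
    "RegistrationTruth",
    "make_phantom",
    "apply_deformation",
    "deformation_map",
    "make_registration_case",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of the synthetic bifurcation.

    Radii and lengths in mm; branch angles are tilts from the z-axis in
    degrees (ICA tilts toward +x, ECA toward -x).  ``branch_length_mm`` is
    the *vertical* (z) extent of the branches, so both branches span the
    same slices.  ``branch_offset_mm`` is the lateral offset of each branch
    axis at the bifurcation; ``None`` picks the smallest offset that keeps
    the two branch contours disjoint in every slice.
    """

    cca_radius_mm: float = 3.0
    ica_radius_mm: float = 2.4
    eca_radius_mm: float = 1.6
    cca_length_mm: float = 20.0
    branch_length_mm: float = 16.0
    branch_angle_ica_deg: float = 25.0
    branch_angle_eca_deg: float = 30.0
    slice_spacing_mm: float = 0.4
    vertices_per_contour: int = 32
    branch_offset_mm: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cca_radius_mm", "ica_radius_mm", "eca_radius_mm",
                     "cca_length_mm", "branch_length_mm", "slice_spacing_mm"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("branch_angle_ica_deg", "branch_angle_eca_deg"):
            if not 0.0 < getattr(self, name) < 60.0:
                raise ValidationError(f"{name} must be in (0, 60) degrees")
        if self.vertices_per_contour < 3:
            raise ValidationError("vertices_per_contour must be >= 3")


@dataclass(frozen=True)
class DeformationSpec:
    """Ground-truth deformation: bend + twist + rigid motion + contour noise.

    The bend displaces x by ``bend_amplitude_mm * sin(2 pi z /
    bend_wavelength_mm)`` (a C-infinity field); the twist rotates each plane
    about the z-axis by ``twist_deg_per_cm * z / 10`` degrees.  Noise is
    zero-mean Gaussian with standard deviation ``noise_sigma_mm``, added
    independently to the x and y coordinate of every contour vertex (never
    to z), after re-slicing.
    """

    rigid: RigidTransform = field(default_factory=RigidTransform.identity)
    bend_amplitude_mm: float = 0.0
    bend_wavelength_mm: float = 40.0
    twist_deg_per_cm: float = 0.0
    noise_sigma_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma_mm < 0:
            raise ValidationError("noise_sigma_mm must be >= 0")
        if not self.bend_wavelength_mm > 0:
            raise ValidationError("bend_wavelength_mm must be positive")


@dataclass
class RegistrationTruth:
    """Everything needed to score a candidate registration against truth."""

    phantom: PhantomSpec
    deformation: DeformationSpec
    rigid: RigidTransform
    displacement_map: Callable[[np.ndarray], np.ndarray]
    labels_by_slice: dict[float, list[str]]

    def to_dict(self) -> dict:
        """JSON-serializable record (the displacement map is reconstructed
        from the specs via :func:`deformation_map`)."""
        p = asdict(self.phantom)
        d = asdict(self.deformation)
        d["rigid"] = self.rigid.to_dict()
        return {"phantom_spec": p, "deformation_spec": d}

    @classmethod
    def from_dict(cls, doc: dict) -> "RegistrationTruth":
        p = PhantomSpec(**doc["phantom_spec"])
        d = dict(doc["deformation_spec"])
        d["rigid"] = RigidTransform.from_dict(d["rigid"])
        spec = DeformationSpec(**d)
        return cls(p, spec, spec.rigid, deformation_map(spec), {})


def _branch_semi_axes(spec: PhantomSpec) -> tuple[float, float]:
    """In-plane x semi-axes of the tilted ICA and ECA cross-sections."""
    a_ica = spec.ica_radius_mm / math.cos(math.radians(spec.branch_angle_ica_deg))
    a_eca = spec.eca_radius_mm / math.cos(math.radians(spec.branch_angle_eca_deg))
    return a_ica, a_eca


def _auto_offset(spec: PhantomSpec) -> float:
    a_ica, a_eca = _branch_semi_axes(spec)
    return 0.5 * (a_ica + a_eca + 0.2)


def make_phantom(spec: PhantomSpec) -> ContourStack:
    """Generate the fully labeled phantom contour stack.

    Slices at z <= cca_length hold one CCA circle centered on the z-axis;
    every slice above holds the ECA ellipse (on the -x side) and the ICA
    ellipse (on the +x side).  Deterministic given the spec.
    """
    offset = spec.branch_offset_mm if spec.branch_offset_mm is not None else _auto_offset(spec)
    a_ica, a_eca = _branch_semi_axes(spec)
    tan_i = math.tan(math.radians(spec.branch_angle_ica_deg))
    tan_e = math.tan(math.radians(spec.branch_angle_eca_deg))

    n = spec.vertices_per_contour
    t = 2.0 * math.pi * np.arange(n) / n
    cos_t, sin_t = np.cos(t), np.sin(t)

    z0 = spec.cca_length_mm
    z_top = z0 + spec.branch_length_mm
    zs = np.arange(0.0, z_top + 1e-9, spec.slice_spacing_mm)

    contours: list[Contour2D] = []
    first_branch_checked = False
    for z in zs:
        if z <= z0 + 1e-12:
            verts = np.column_stack([spec.cca_radius_mm * cos_t, spec.cca_radius_mm * sin_t])
            contours.append(Contour2D(float(z), verts, VesselLabel.CCA))
        else:
            dz = z - z0
            cx_ica = offset + dz * tan_i
            cx_eca = -offset - dz * tan_e
            ica = np.column_stack(
                [cx_ica + a_ica * cos_t, spec.ica_radius_mm * sin_t]
            )
            eca = np.column_stack(
                [cx_eca + a_eca * cos_t, spec.eca_radius_mm * sin_t]
            )
            if not first_branch_checked:
                gap = (cx_ica - a_ica) - (cx_eca + a_eca)
                if gap <= 0:
                    raise ValidationError(
                        "branch contours overlap at the first bifurcation slice; "
                        "increase branch_offset_mm or the branch angles"
                    )
                first_branch_checked = True
            contours.append(Contour2D(float(z), eca, VesselLabel.ECA))
            contours.append(Contour2D(float(z), ica, VesselLabel.ICA))
    return ContourStack(contours, spec.slice_spacing_mm, source_tag="phantom")


def deformation_map(d: DeformationSpec) -> Callable[[np.ndarray], np.ndarray]:
    """Noiseless ground-truth displacement map: bend, then twist, then the
    rigid motion, applied to arbitrary (N, 3) points."""

    def apply(points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float)).copy()
        z = pts[:, 2]
        if d.bend_amplitude_mm != 0.0:
            pts[:, 0] = pts[:, 0] + d.bend_amplitude_mm * np.sin(
                2.0 * np.pi * z / d.bend_wavelength_mm
            )
        if d.twist_deg_per_cm != 0.0:
            phi = np.radians(d.twist_deg_per_cm * z / 10.0)
            c, s = np.cos(phi), np.sin(phi)
            x, y = pts[:, 0].copy(), pts[:, 1].copy()
            pts[:, 0] = c * x - s * y
            pts[:, 1] = s * x + c * y
        return d.rigid.apply(pts)

    return apply


def apply_deformation(
    stack: ContourStack, d: DeformationSpec
) -> tuple[ContourStack, Callable[[np.ndarray], np.ndarray]]:
    """Deform a stack and re-express it as per-slice contours.

    Requires every contour of a vessel to share the same vertex count (true
    for generated phantoms), so corresponding vertices form tracks along the
    vessel.  Each track is deformed in 3D and linearly re-sliced at the
    original z positions; a slice keeps a vessel's contour only where every
    track of that vessel covers it.  Gaussian in-plane noise (if any) is
    added to the re-sliced vertices.  Returns the deformed stack and the
    noiseless ground-truth map.
    """
    gmap = deformation_map(d)
    target_z = stack.z_values
    rng = np.random.default_rng(d.seed)

    new_contours: list[Contour2D] = []
    # canonical in-slice order (CCA, ECA, ICA) — matches make_phantom, so an
    # identity deformation reproduces the stack contour-for-contour
    for label in (VesselLabel.CCA, VesselLabel.ECA, VesselLabel.ICA, VesselLabel.UNLABELED):
        contours = stack.contours_for(label)
        if not contours:
            continue
        counts = {c.n_vertices for c in contours}
        if len(counts) != 1:
            raise ValidationError(
                f"vessel {label.name}: contours must share a vertex count to deform"
            )
        nv = counts.pop()
        rings = np.stack(
            [np.column_stack([c.vertices, np.full(nv, c.z_mm)]) for c in contours]
        )  # (n_slices, nv, 3)
        deformed = gmap(rings.reshape(-1, 3)).reshape(rings.shape)

        if len(contours) == 1:
            ring = deformed[0]
            z_new = float(np.mean(ring[:, 2]))
            new_contours.append(Contour2D(z_new, ring[:, :2], label))
            continue

        track_z = deformed[:, :, 2]  # (n_slices, nv)
        dz = np.diff(track_z, axis=0)
        if np.any(dz <= 0):
            raise ValidationError(
                "deformation too severe: a vertex track is not monotone in z; "
                "reduce the rotation/bend magnitude"
            )
        z_lo = float(track_z[0].max())
        z_hi = float(track_z[-1].min())
        covered = target_z[(target_z >= z_lo - 1e-9) & (target_z <= z_hi + 1e-9)]
        if covered.size == 0:
            continue
        resliced = np.empty((covered.size, nv, 2))
        for j in range(nv):
            resliced[:, j, 0] = np.interp(covered, track_z[:, j], deformed[:, j, 0])
            resliced[:, j, 1] = np.interp(covered, track_z[:, j], deformed[:, j, 1])
        if d.noise_sigma_mm > 0:
            resliced = resliced + rng.normal(0.0, d.noise_sigma_mm, size=resliced.shape)
        for z, verts in zip(covered, resliced):
            new_contours.append(Contour2D(float(z), verts, label))
    if not new_contours:
        raise ValidationError("deformation moved every contour out of the slice range")
    return ContourStack(new_contours, stack.slice_spacing_mm, stack.source_tag), gmap


def make_registration_case(
    phantom: PhantomSpec,
    deform: DeformationSpec,
    unlabel_moving: bool = False,
) -> tuple[ContourStack, ContourStack, RegistrationTruth]:
    """Build a (fixed, moving, truth) registration case.

    ``fixed`` is the undeformed labeled phantom (its labels follow the
    ECA-ICA in-slice convention by construction); ``moving`` is the deformed
    phantom, with labels stripped iff ``unlabel_moving``.
    """
    fixed = make_phantom(phantom)
    moving, gmap = apply_deformation(fixed, deform)
    labels_by_slice = {
        z: [c.label.name for c in group] for z, group in moving.slices()
    }
    if unlabel_moving:
        moving = ContourStack(
            [c.with_label(VesselLabel.UNLABELED) for c in moving.contours],
            moving.slice_spacing_mm,
            moving.source_tag,
        )
    truth = RegistrationTruth(
        phantom=phantom,
        deformation=deform,
        rigid=deform.rigid,
        displacement_map=gmap,
        labels_by_slice=labels_by_slice,
    )
    return fixed, moving, truth
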