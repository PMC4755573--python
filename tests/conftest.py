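import numpy as np
import pytest

from tacicp import (
    Contour2D,
    ContourStack,
    DeformationSpec,
    PhantomSpec,
    RigidTransform,
    VesselLabel,
    make_phantom,
)


def regular_polygon(n: int, radius: float = 1.0, center=(0.0, 0.0), phase: float = 0.0):
    t = phase + 2 * np.pi * np.arange(n) / n
    return np.column_stack([center[0] + radius * np.cos(t), center[1] + radius * np.sin(t)])


def random_star_polygon(rng: np.random.Generator, n: int = 12, scale: float = 3.0):
    """Random simple (star-shaped) polygon around a random center."""
    t = np.sort(rng.uniform(0, 2 * np.pi, n))
    r = rng.uniform(0.4, 1.0, n) * scale
    c = rng.uniform(-2, 2, 2)
    return np.column_stack([c[0] + r * np.cos(t), c[1] + r * np.sin(t)])


def random_rigid(rng: np.random.Generator, max_angle_deg: float, max_translation: float):
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0.0, max_angle_deg)
    t = rng.uniform(-max_translation, max_translation, 3)
    return RigidTransform.from_rotvec(axis * angle, t)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def fast_phantom_spec():
    """Coarse phantom used throughout the suite (fast to build and register)."""
    return PhantomSpec(slice_spacing_mm=0.8)


@pytest.fixture
def fast_phantom(fast_phantom_spec):
    return make_phantom(fast_phantom_spec)


@pytest.fixture
def tiny_stack():
    """Minimal labeled stack: a short straight tube, 5 slices."""
    contours = [
        Contour2D(float(z), regular_polygon(12, radius=2.0), VesselLabel.CCA)
        for z in range(5)
    ]
    return ContourStack(contours, slice_spacing_mm=1.0, source_tag="tiny")


def bend_twist_deform(rng: np.random.Generator, seed: int = 0) -> DeformationSpec:
    """A representative non-rigid truth deformation with a moderate rigid part."""
    return DeformationSpec(
        rigid=random_rigid(rng, 15.0, 5.0),
        bend_amplitude_mm=float(rng.uniform(0.8, 2.0)),
        bend_wavelength_mm=float(rng.uniform(35.0, 60.0)),
        twist_deg_per_cm=float(rng.uniform(2.0, 6.0)),
        seed=seed,
    )
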