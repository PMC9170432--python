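"""Seeded synthetic data: mixture draws and brain-like phantom images.

The phantom emulates the appearance the segmentation pipeline targets — a
dark background, an elliptical "brain" of near-constant parenchyma
intensity and a hyperintense lesion inside it (FLAIR-like contrast on a
0-255 scale, default class means 20 / 110 / 200) — corrupted by additive
Gaussian noise and optionally by a smooth multiplicative bias field and an
edge-blurring kernel.  Every output is a pure function of its spec and
seed and carries the exact ground-truth masks, so segmentation quality can
be scored without clinical data.

What the phantom does NOT emulate: Rician noise statistics, partial-volume
mixtures beyond the blur kernel, multi-sequence contrast, or anatomical
texture; passing tests bound algorithmic correctness, not clinical
performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
from scipy import ndimage

from .mixture import GMMParams, SampleSet

__all__ = [
    "LesionGeometry",
    "PhantomSpec",
    "PhantomSample",
    "simulate_gmm_samples",
    "generate_phantom",
    "phantom_suite",
    "BACKGROUND", "PARENCHYMA", "LESION",
]

BACKGROUND, PARENCHYMA, LESION = 0, 1, 2


@dataclass(frozen=True)
class LesionGeometry:
    """Lesion placement: center and radii in pixels; ellipse or bumpy blob."""

    center: tuple = (44.0, 74.0)
    radii: tuple = (12.0, 9.0)
    shape: str = "ellipse"

    def __post_init__(self):
        if self.shape not in ("ellipse", "blob"):
            raise ValueError(f"unknown lesion shape: {self.shape}")
        if min(self.radii) <= 0:
            raise ValueError("lesion radii must be positive")


@dataclass(frozen=True)
class PhantomSpec:
    """Generation recipe for one phantom image.

    ``class_means`` are (background, parenchyma, lesion) intensities on a
    0-255 scale; ``noise_sigma`` is the additive Gaussian noise level;
    ``bias_field_amplitude`` scales a low-order polynomial multiplicative
    field (fraction of unity, 0 disables); ``edge_blur_sigma`` blurs the
    piecewise-constant image before noise, producing weak edges while the
    truth mask stays exact.
    """

    shape: tuple = (128, 128)
    class_means: tuple = (20.0, 110.0, 200.0)
    noise_sigma: float = 9.0
    lesion_geometry: LesionGeometry = field(default_factory=LesionGeometry)
    bias_field_amplitude: float = 0.0
    edge_blur_sigma: float = 0.0
    brain_radii_frac: tuple = (0.42, 0.38)
    seed: int = 0

    def __post_init__(self):
        if len(set(self.class_means)) != len(self.class_means):
            raise ValueError("class means must be pairwise distinct")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.bias_field_amplitude < 0:
            raise ValueError("bias_field_amplitude must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PhantomSample:
    """Synthetic image with its exact ground truth."""

    image: np.ndarray
    truth_mask: np.ndarray
    label_map: np.ndarray
    spec: PhantomSpec


def simulate_gmm_samples(params: GMMParams, n: int, seed: int = 0):
    """Draw n values from the mixture; returns (SampleSet, assignments).

    Component per sample is drawn from the mixing coefficients, then the
    value from that component's normal; the true assignments are returned
    for parameter-recovery tests.  Deterministic per seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    assignments = rng.choice(params.L, size=n, p=params.pis)
    values = rng.normal(params.mus[assignments],
                        np.sqrt(params.sigma2s[assignments]))
    return SampleSet.from_values(values), assignments


def _ellipse_mask(shape, center, radii) -> np.ndarray:
    grids = np.indices(shape).astype(float)
    q = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return q <= 1.0


def _blob_mask(shape, center, radii, rng) -> np.ndarray:
    """Ellipse with a smooth seeded radial perturbation (bumpy lesion)."""
    rr, cc = np.indices(shape).astype(float)
    dr, dc = rr - center[0], cc - center[1]
    theta = np.arctan2(dc, dr)
    n_modes = 4
    amps = rng.uniform(-0.18, 0.18, size=n_modes)
    phases = rng.uniform(0, 2 * np.pi, size=n_modes)
    wobble = 1.0 + sum(a * np.cos((k + 2) * theta + p)
                       for k, (a, p) in enumerate(zip(amps, phases)))
    q = (dr / radii[0]) ** 2 + (dc / radii[1]) ** 2
    return q <= wobble**2


def _bias_field(shape, amplitude, rng) -> np.ndarray:
    """Smooth multiplicative field 1 + amplitude * P(x, y), P a low-order
    polynomial with seeded coefficients, normalized to [-1, 1]."""
    grids = [np.linspace(-1.0, 1.0, s) for s in shape]
    mesh = np.meshgrid(*grids, indexing="ij")
    coeffs = rng.uniform(-1.0, 1.0, size=6)
    x, y = mesh[0], mesh[-1]
    poly = (coeffs[0] * x + coeffs[1] * y + coeffs[2] * x * y
            + coeffs[3] * x**2 + coeffs[4] * y**2 + coeffs[5])
    span = np.abs(poly).max() + 1e-12
    return 1.0 + amplitude * poly / span


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Render the phantom image and its exact ground-truth masks."""
    shape = tuple(int(s) for s in spec.shape)
    center = tuple((s - 1) / 2.0 for s in shape)
    brain_radii = tuple(f * s for f, s in zip(spec.brain_radii_frac, shape))
    rng = np.random.default_rng(spec.seed)

    label_map = np.full(shape, BACKGROUND, dtype=np.int8)
    brain = _ellipse_mask(shape, center, brain_radii)
    label_map[brain] = PARENCHYMA
    geom = spec.lesion_geometry
    if geom.shape == "ellipse":
        lesion = _ellipse_mask(shape, geom.center, geom.radii)
    else:
        lesion = _blob_mask(shape, geom.center, geom.radii, rng)
    if not lesion.any():
        raise ValueError("lesion mask is empty")
    if np.any(lesion & ~brain):
        raise ValueError("lesion extends outside the brain region")
    label_map[lesion] = LESION

    image = np.asarray(spec.class_means, dtype=float)[label_map]
    if spec.edge_blur_sigma > 0:
        image = ndimage.gaussian_filter(image, spec.edge_blur_sigma)
    if spec.bias_field_amplitude > 0:
        image = image * _bias_field(shape, spec.bias_field_amplitude, rng)
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=shape)

    return PhantomSample(image=image, truth_mask=label_map == LESION,
                         label_map=label_map, spec=spec)


_DIFFICULTIES = ("crisp", "weak-edge", "noisy")


def phantom_suite(n_images: int, difficulty: str = "crisp", seed: int = 0,
                  shape=(96, 96)) -> list:
    """Seeded suite of phantoms with per-image randomized lesions.

    Difficulty presets:

    - ``crisp``: sharp class boundaries, light noise (sigma in [1, 4]);
    - ``weak-edge``: pre-noise Gaussian blur of the class image
      (sigma in [2, 3.5]) plus mild noise — shallow gradient edges;
    - ``noisy``: noise_sigma = 20% of the smallest class contrast.

    Per-image seeds derive deterministically from the master seed.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    if difficulty not in _DIFFICULTIES:
        raise ValueError(f"difficulty must be one of {_DIFFICULTIES}")
    shape = tuple(int(s) for s in shape)
    master = np.random.default_rng(seed)
    samples = []
    class_means = (20.0, 110.0, 200.0)
    min_contrast = min(np.diff(sorted(class_means)))
    center0 = tuple((s - 1) / 2.0 for s in shape)
    for k in range(n_images):
        sub = int(master.integers(0, 2**31 - 1))
        rng = np.random.default_rng(sub)
        radii = tuple(rng.uniform(0.08, 0.14) * min(shape) for _ in range(2))
        # keep the lesion well inside the brain ellipse
        max_off = 0.16 * min(shape)
        offset = rng.uniform(-max_off, max_off, size=2)
        geom = LesionGeometry(
            center=(center0[0] + offset[0], center0[1] + offset[1]),
            radii=radii,
            shape="blob" if rng.random() < 0.5 else "ellipse")
        if difficulty == "crisp":
            noise, blur = rng.uniform(1.0, 4.0), 0.0
        elif difficulty == "weak-edge":
            noise, blur = rng.uniform(4.0, 8.0), rng.uniform(2.0, 3.5)
        else:
            noise, blur = 0.2 * min_contrast, 0.0
        spec = PhantomSpec(shape=shape, class_means=class_means,
                           noise_sigma=float(noise),
                           lesion_geometry=geom,
                           edge_blur_sigma=float(blur), seed=sub)
        samples.append(generate_phantom(spec))
    return samples
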