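"""Synthetic head phantoms with exact ground truth.

Each phantom is a co-registered T1-like / FLAIR-like pair built from analytic
shapes: an ellipsoidal brain, a bright skull-like shell around it, and
spherical white-matter lesions inside the brain that are hyperintense on
FLAIR and hypointense on T1 (the contrast behaviour of MS lesions). On top of
the clean geometry the generator injects the nuisances the preprocessing
chain must undo — additive Gaussian noise, a smooth multiplicative bias
field, and a known in-plane rigid misalignment of the FLAIR volume — while
the ground-truth brain and lesion masks stay clean and exact.

No MR physics is simulated (no sequence model, partial volume, or Rician
noise); the phantoms exist to make every pipeline stage testable against an
analytic answer, not to look like real scans.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .metrics import lesion_volume
from .preprocess import RigidTransform2D, apply_transform
from .volume import BinaryMask, Volume

__all__ = ["PhantomSpec", "PhantomCase", "make_phantom", "make_dataset"]


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Geometry, contrast and nuisance parameters of one phantom.

    Defaults give a 64x64x16 grid at 1 mm³ — small enough to train the
    networks on a single CPU while exercising every pipeline stage.
    """

    shape: tuple[int, int, int] = (64, 64, 16)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    brain_semiaxes: tuple[float, float, float] = (22.0, 18.0, 6.0)  # mm
    skull_thickness: float = 2.5  # mm
    lesion_count_range: tuple[int, int] = (1, 4)
    lesion_radius_range: tuple[float, float] = (2.0, 4.5)  # mm
    # clean tissue intensities (arbitrary units)
    t1_background: float = 0.05
    t1_brain: float = 0.60
    t1_skull: float = 0.90
    t1_lesion: float = 0.35          # hypointense on T1
    flair_background: float = 0.05
    flair_brain: float = 0.50
    flair_skull: float = 0.25        # suppressed, darker than brain
    flair_lesion: float = 0.90       # hyperintense on FLAIR
    noise_sigma: float = 0.02
    bias_amplitude: float = 0.2      # field spans roughly [1-amp, 1+amp]
    bias_order: int = 2
    max_shift_mm: float = 3.0        # |tx|, |ty| bound of FLAIR misalignment
    max_rotation_rad: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lesion_radius_range[0] <= 0:
            raise ValueError("lesion radius must be positive")
        if self.t1_brain - self.t1_lesion <= 0 or self.flair_lesion - self.flair_brain <= 0:
            raise ValueError("lesion contrasts must be positive (hypo-T1 / hyper-FLAIR)")


@dataclasses.dataclass
class PhantomCase:
    """One generated phantom with its exact ground truth."""

    t1: Volume
    flair: Volume
    brain_truth: BinaryMask
    lesion_truth: BinaryMask
    true_lesion_volume_mm3: float
    injected_transform: RigidTransform2D
    injected_bias: Volume
    spec: PhantomSpec
    lesion_spheres: list = dataclasses.field(default_factory=list)
    """Analytic lesion geometry: (cx, cy, cz, radius) in mm per placed sphere."""


def _mm_grids(spec: PhantomSpec):
    idx = [np.arange(n, dtype=np.float64) * s
           for n, s in zip(spec.shape, spec.spacing)]
    return np.meshgrid(*idx, indexing="ij")


def _ellipsoid(X, Y, Z, center, semiaxes) -> np.ndarray:
    q = ((X - center[0]) / semiaxes[0]) ** 2 \
        + ((Y - center[1]) / semiaxes[1]) ** 2 \
        + ((Z - center[2]) / semiaxes[2]) ** 2
    return q <= 1.0


def _bias_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth random polynomial field ~ 1 + amplitude * f, max|f| = 1."""
    axes = [np.linspace(-1.0, 1.0, n) if n > 1 else np.zeros(n) for n in spec.shape]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    f = np.zeros(spec.shape)
    for deg in range(1, spec.bias_order + 1):
        for term in (X, Y, Z):
            f += rng.uniform(-1.0, 1.0) * term ** deg
        if deg >= 2:
            f += rng.uniform(-1.0, 1.0) * X * Y
    peak = np.abs(f).max()
    if peak > 0:
        f /= peak
    return 1.0 + spec.bias_amplitude * f


def make_phantom(spec: PhantomSpec) -> PhantomCase:
    """Generate one phantom deterministically from ``spec.seed``.

    Lesion centres are rejection-sampled so each sphere lies entirely inside
    the brain ellipsoid; a sphere that cannot be placed within 200 attempts
    raises (the requested geometry cannot be realised).
    """
    rng = np.random.default_rng(spec.seed)
    X, Y, Z = _mm_grids(spec)
    extent = [(n - 1) * s for n, s in zip(spec.shape, spec.spacing)]
    center = [e / 2.0 for e in extent]

    brain = _ellipsoid(X, Y, Z, center, spec.brain_semiaxes)
    outer = [a + spec.skull_thickness for a in spec.brain_semiaxes]
    skull = _ellipsoid(X, Y, Z, center, outer) & ~brain

    # --- lesions -----------------------------------------------------------
    n_lesions = int(rng.integers(spec.lesion_count_range[0],
                                 spec.lesion_count_range[1] + 1))
    lesion = np.zeros(spec.shape, dtype=bool)
    spheres: list[tuple[float, float, float, float]] = []
    for _ in range(n_lesions):
        placed = False
        for _attempt in range(200):
            r = rng.uniform(*spec.lesion_radius_range)
            # sphere fits iff its centre is inside the ellipsoid shrunk by r
            shrunk = [a - r for a in spec.brain_semiaxes]
            if min(shrunk) <= 0:
                continue
            c = [center[i] + rng.uniform(-spec.brain_semiaxes[i], spec.brain_semiaxes[i])
                 for i in range(3)]
            q = sum(((c[i] - center[i]) / shrunk[i]) ** 2 for i in range(3))
            if q > 1.0:
                continue
            ball = (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2 <= r * r
            lesion |= ball
            spheres.append((c[0], c[1], c[2], r))
            placed = True
            break
        if not placed:
            raise RuntimeError("could not place a lesion inside the brain ellipsoid")
    lesion &= brain  # guaranteed already, but keeps the invariant explicit

    # --- clean intensity images (FLAIR in the T1-aligned frame) ------------
    t1 = np.full(spec.shape, spec.t1_background)
    t1[skull] = spec.t1_skull
    t1[brain] = spec.t1_brain
    t1[lesion] = spec.t1_lesion

    flair = np.full(spec.shape, spec.flair_background)
    flair[skull] = spec.flair_skull
    flair[brain] = spec.flair_brain
    flair[lesion] = spec.flair_lesion

    # --- nuisances ----------------------------------------------------------
    T = RigidTransform2D(
        tx=float(rng.uniform(-spec.max_shift_mm, spec.max_shift_mm)),
        ty=float(rng.uniform(-spec.max_shift_mm, spec.max_shift_mm)),
        theta=float(rng.uniform(-spec.max_rotation_rad, spec.max_rotation_rad)),
    )
    flair_v = Volume(flair, spec.spacing)
    if (T.tx, T.ty, T.theta) != (0.0, 0.0, 0.0):
        flair_v = apply_transform(flair_v, T, interpolation="spline")
        flair = np.clip(flair_v.data, 0.0, None)

    field = _bias_field(spec, rng)
    t1 = t1 * field
    flair = flair * field

    if spec.noise_sigma > 0:
        t1 = t1 + rng.normal(0.0, spec.noise_sigma, spec.shape)
        flair = flair + rng.normal(0.0, spec.noise_sigma, spec.shape)

    brain_mask = BinaryMask(brain.astype(np.uint8), spec.spacing)
    lesion_mask = BinaryMask(lesion.astype(np.uint8), spec.spacing)
    return PhantomCase(
        t1=Volume(t1, spec.spacing),
        flair=Volume(flair, spec.spacing),
        brain_truth=brain_mask,
        lesion_truth=lesion_mask,
        true_lesion_volume_mm3=lesion_volume(lesion_mask),
        injected_transform=T,
        injected_bias=Volume(field, spec.spacing),
        spec=spec,
        lesion_spheres=spheres,
    )


def make_dataset(n: int, spec: PhantomSpec, seed: int) -> list[PhantomCase]:
    """Generate ``n`` phantoms with independent per-case seeds (reproducible)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n)
    cases = []
    for child in children:
        case_seed = int(child.generate_state(1)[0] % (2 ** 31))
        cases.append(make_phantom(dataclasses.replace(spec, seed=case_seed)))
    return cases
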