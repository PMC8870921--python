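"""Preprocessing chain for paired T1-w / FLAIR volumes.

Steps mirror a standard MS-MRI pipeline: (1) reslice to isotropic 1 mm³ with
cubic splines, (2) edge-preserving Perona–Malik anisotropic diffusion
slice-wise, (3) in-plane rigid registration of FLAIR onto T1-w (slices paired
by index, one transform per volume) by normalised mutual information,
(4) per-slice z-score normalisation, (5) skull-stripping via the brain mask
(see the unet / inference modules), (6) multiplicative bias-field correction
using a log-domain polynomial surface fit inside the brain mask, plus the
in-plane resize and global [0, 1] rescale used to feed the networks.

All image resampling is cubic spline; all mask resampling is
nearest-neighbour, so masks stay binary through every operation. The chain is
fully deterministic.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from itertools import combinations_with_replacement

import numpy as np
from scipy import ndimage, optimize

from .volume import BinaryMask, ProbabilityMap, Volume

__all__ = [
    "RigidTransform2D",
    "DiffusionConfig",
    "reslice_isotropic",
    "anisotropic_diffuse",
    "register_rigid_inplane",
    "apply_transform",
    "zscore_normalize",
    "minmax_rescale",
    "resize_inplane",
    "estimate_bias_field",
    "correct_bias",
    "apply_mask",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# rigid in-plane transforms
# ---------------------------------------------------------------------------

def _wrap_angle(theta: float) -> float:
    """Wrap an angle to (-pi, pi]."""
    t = math.fmod(theta + math.pi, 2 * math.pi)
    if t <= 0:
        t += 2 * math.pi
    return t - math.pi


@dataclasses.dataclass(frozen=True)
class RigidTransform2D:
    """In-plane rigid motion: rotate ``theta`` about the slice centre, then
    translate by (``tx``, ``ty``) millimetres along the row/column axes.

    The same transform is applied to every slice of a volume (slices are
    paired by index across modalities).
    """

    tx: float = 0.0
    ty: float = 0.0
    theta: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "theta", _wrap_angle(float(self.theta)))

    def _rot(self, sign: float = 1.0) -> np.ndarray:
        c, s = math.cos(sign * self.theta), math.sin(sign * self.theta)
        return np.array([[c, -s], [s, c]])

    def inverse(self) -> "RigidTransform2D":
        t = self._rot(-1.0) @ np.array([self.tx, self.ty])
        return RigidTransform2D(-t[0], -t[1], -self.theta)

    def compose(self, first: "RigidTransform2D") -> "RigidTransform2D":
        """Transform equivalent to applying ``first`` then ``self``."""
        t = self._rot() @ np.array([first.tx, first.ty]) + np.array([self.tx, self.ty])
        return RigidTransform2D(t[0], t[1], self.theta + first.theta)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.tx, self.ty, self.theta)


@dataclasses.dataclass
class DiffusionConfig:
    """Perona–Malik diffusion parameters.

    ``kappa`` is the conductance scale. With ``relative=True`` (default) it
    is a percentage of each slice's intensity range, so "kappa 15" means the
    same thing on a [0, 1]-rescaled image as on a raw scanner-unit volume;
    with ``relative=False`` it is in absolute intensity units. The explicit
    2D scheme is stable for ``dt`` up to 0.25.
    """

    iterations: int = 10
    kappa: float = 15.0
    dt: float = 0.125
    conductance: str = "exponential"  # or "rational"
    relative: bool = True

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if not (0 < self.dt <= 0.25):
            raise ValueError(f"dt must be in (0, 0.25], got {self.dt}")
        if self.conductance not in ("exponential", "rational"):
            raise ValueError(f"unknown conductance: {self.conductance}")


# ---------------------------------------------------------------------------
# resampling helpers
# ---------------------------------------------------------------------------

def _interp_order(v: Volume, interpolation: str | None = None) -> int:
    if isinstance(v, BinaryMask):
        return 0
    if interpolation == "nearest":
        return 0
    return 3


def _rewrap(v: Volume, data: np.ndarray, spacing=None, clip_range: bool = False) -> Volume:
    spacing = v.spacing if spacing is None else spacing
    if isinstance(v, BinaryMask):
        return BinaryMask(np.rint(data).astype(np.uint8), spacing, v.affine)
    if isinstance(v, ProbabilityMap):
        return ProbabilityMap(np.clip(data, 0.0, 1.0), spacing, v.affine)
    if clip_range:
        # suppress cubic-spline over/undershoot at sharp edges: resampling
        # must not extend the intensity range of the input
        data = np.clip(data, v.data.min(), v.data.max())
    return Volume(data, spacing, v.affine)


def reslice_isotropic(v: Volume, target: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> Volume:
    """Resample to the target spacing (default isotropic 1 mm³).

    Images use cubic spline interpolation, masks nearest-neighbour. The
    output grid has round(shape · spacing / target) voxels per axis, so the
    physical extent is preserved to within one voxel per axis.
    """
    if any(t <= 0 for t in target):
        raise ValueError(f"target spacing must be positive, got {target}")
    factors = [s / t for s, t in zip(v.spacing, target)]
    order = _interp_order(v)
    data = ndimage.zoom(v.data.astype(np.float64), factors, order=order,
                        mode="nearest", grid_mode=True)
    return _rewrap(v, data, spacing=tuple(target), clip_range=order > 1)


def resize_inplane(v: Volume, size: tuple[int, int]) -> Volume:
    """Resample every slice to ``size`` (rows, cols), keeping physical extent.

    The in-plane spacing is rescaled so rows·sx and cols·sy are unchanged.
    """
    rows, cols = size
    if rows <= 0 or cols <= 0:
        raise ValueError(f"size must be positive, got {size}")
    r0, c0, _ = v.shape
    if (r0, c0) == (rows, cols):
        return v.copy()
    factors = [rows / r0, cols / c0, 1.0]
    order = _interp_order(v)
    data = ndimage.zoom(v.data.astype(np.float64), factors, order=order,
                        mode="nearest", grid_mode=True)
    sx, sy, sz = v.spacing
    return _rewrap(v, data, spacing=(sx * r0 / rows, sy * c0 / cols, sz),
                   clip_range=order > 1)


def apply_transform(v: Volume, T: RigidTransform2D, interpolation: str = "spline") -> Volume:
    """Resample every slice under the in-plane rigid transform ``T``.

    Masks (or ``interpolation='nearest'``) use nearest-neighbour so binary
    values survive; images use cubic splines. Out-of-field voxels are filled
    with the edge value's nearest sample (constant 0 background in practice).
    """
    order = _interp_order(v, interpolation)
    sx, sy, _ = v.spacing
    rows, cols = v.shape[:2]
    c = np.array([(rows - 1) / 2.0, (cols - 1) / 2.0])
    S = np.diag([sx, sy])
    Sinv = np.diag([1.0 / sx, 1.0 / sy])
    Rinv = T._rot(-1.0)
    t = np.array([T.tx, T.ty])
    M2 = Sinv @ Rinv @ S
    off2 = c - Sinv @ Rinv @ (S @ c + t)
    M = np.eye(3)
    M[:2, :2] = M2
    offset = np.array([off2[0], off2[1], 0.0])
    data = ndimage.affine_transform(v.data.astype(np.float64), M, offset=offset,
                                    order=order, mode="constant", cval=0.0)
    return _rewrap(v, data, clip_range=order > 1)


# ---------------------------------------------------------------------------
# anisotropic diffusion
# ---------------------------------------------------------------------------

def _conductance(d: np.ndarray, kappa: float, kind: str) -> np.ndarray:
    a = d / kappa
    if kind == "exponential":
        return np.exp(-(a * a))
    return 1.0 / (1.0 + a * a)


def _diffuse_slice(im: np.ndarray, cfg: DiffusionConfig) -> np.ndarray:
    # Flux form of the explicit Perona-Malik scheme: each inter-pixel flux is
    # applied antisymmetrically, so the intensity sum is conserved exactly and
    # the zero-flux (Neumann) boundary is implicit.
    out = im.astype(np.float64, copy=True)
    if cfg.relative:
        kappa = cfg.kappa / 100.0 * max(np.ptp(im), 1e-12)
    else:
        kappa = cfg.kappa
    for _ in range(cfg.iterations):
        d0 = np.diff(out, axis=0)
        f0 = _conductance(np.abs(d0), kappa, cfg.conductance) * d0
        d1 = np.diff(out, axis=1)
        f1 = _conductance(np.abs(d1), kappa, cfg.conductance) * d1
        out[:-1, :] += cfg.dt * f0
        out[1:, :] -= cfg.dt * f0
        out[:, :-1] += cfg.dt * f1
        out[:, 1:] -= cfg.dt * f1
    return out


def anisotropic_diffuse(v: Volume, cfg: DiffusionConfig | None = None) -> Volume:
    """Slice-wise Perona–Malik edge-preserving smoothing.

    The diffusion coefficient g(|∇I|; kappa) decays with the local gradient,
    so smoothing happens within regions rather than across edges. Constant
    images are fixed points; the per-slice intensity sum is conserved.
    """
    cfg = cfg or DiffusionConfig()
    out = np.empty_like(v.data, dtype=np.float64)
    for k in range(v.shape[2]):
        out[:, :, k] = _diffuse_slice(v.data[:, :, k], cfg)
    return Volume(out, v.spacing, v.affine)


# ---------------------------------------------------------------------------
# rigid registration (normalised mutual information)
# ---------------------------------------------------------------------------

def _nmi(a: np.ndarray, b: np.ndarray, bins: int = 32) -> float:
    """Normalised mutual information (H(A)+H(B))/H(A,B).

    The joint histogram uses partial-volume (bilinear) binning: each sample
    spreads over its four neighbouring bins, which makes the similarity
    surface smooth in the transform parameters — a hard histogram is
    piecewise constant in sub-bin shifts and stalls the optimiser.
    """
    a = a.ravel()
    b = b.ravel()
    fa = (a - a.min()) / max(np.ptp(a), 1e-12) * (bins - 1)
    fb = (b - b.min()) / max(np.ptp(b), 1e-12) * (bins - 1)
    ia = np.clip(fa.astype(np.int64), 0, bins - 2)
    ib = np.clip(fb.astype(np.int64), 0, bins - 2)
    ra = fa - ia
    rb = fb - ib
    hist = np.zeros(bins * bins)
    for da, wa in ((0, 1 - ra), (1, ra)):
        for db, wb in ((0, 1 - rb), (1, rb)):
            hist += np.bincount((ia + da) * bins + (ib + db), weights=wa * wb,
                                minlength=bins * bins)
    p = hist / hist.sum()
    nz = p > 0
    hxy = -np.sum(p[nz] * np.log(p[nz]))
    px = p.reshape(bins, bins).sum(axis=1)
    py = p.reshape(bins, bins).sum(axis=0)
    hx = -np.sum(px[px > 0] * np.log(px[px > 0]))
    hy = -np.sum(py[py > 0] * np.log(py[py > 0]))
    if hxy == 0:
        return 2.0
    return (hx + hy) / hxy


_THETA_SCALE = 50.0  # mm lever arm: makes Powell steps in rad comparable to mm


def _downsample_inplane(data: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return data
    sm = ndimage.uniform_filter(data, size=(factor, factor, 1), mode="nearest")
    return sm[::factor, ::factor, :]


def register_rigid_inplane(
    moving: Volume,
    fixed: Volume,
    bins: int = 32,
    levels: tuple[int, ...] = (4, 2, 1),
    max_iter: int = 80,
) -> tuple[RigidTransform2D, Volume]:
    """Recover the single in-plane rigid transform aligning ``moving`` to ``fixed``.

    Maximises normalised mutual information (robust across MR contrasts) over
    (tx, ty, theta) with a gradient-free Powell search on a coarse-to-fine
    in-plane pyramid. Both volumes must already share grid shape and spacing
    (call after reslicing); slices correspond by index.

    Returns the transform and the moving volume resampled under it (cubic
    spline).
    """
    if moving.shape != fixed.shape or moving.spacing != fixed.spacing:
        raise ValueError(
            f"moving and fixed must share shape and spacing: "
            f"{moving.shape}/{moving.spacing} vs {fixed.shape}/{fixed.spacing}"
        )
    params = np.zeros(3)
    for level in levels:
        fix = _downsample_inplane(fixed.data.astype(np.float64), level)
        mov = _downsample_inplane(moving.data.astype(np.float64), level)
        sp = (moving.spacing[0] * level, moving.spacing[1] * level, moving.spacing[2])
        mov_v = Volume(mov, sp)

        def neg_nmi(p: np.ndarray) -> float:
            T = RigidTransform2D(p[0], p[1], p[2] / _THETA_SCALE)
            # linear interpolation during the search: cheap and smooth enough
            warped = _warp_linear(mov_v, T)
            return -_nmi(warped, fix, bins=bins)

        res = optimize.minimize(
            neg_nmi,
            params,
            method="Powell",
            options={"maxiter": max_iter, "xtol": 1e-4, "ftol": 1e-9},
        )
        params = res.x
    T = RigidTransform2D(params[0], params[1], params[2] / _THETA_SCALE)
    return T, apply_transform(moving, T)


def _warp_linear(v: Volume, T: RigidTransform2D) -> np.ndarray:
    sx, sy, _ = v.spacing
    rows, cols = v.shape[:2]
    c = np.array([(rows - 1) / 2.0, (cols - 1) / 2.0])
    S = np.diag([sx, sy])
    Sinv = np.diag([1.0 / sx, 1.0 / sy])
    Rinv = T._rot(-1.0)
    t = np.array([T.tx, T.ty])
    M = np.eye(3)
    M[:2, :2] = Sinv @ Rinv @ S
    off2 = c - Sinv @ Rinv @ (S @ c + t)
    return ndimage.affine_transform(v.data, M, offset=np.array([off2[0], off2[1], 0.0]),
                                    order=1, mode="constant", cval=0.0)


# ---------------------------------------------------------------------------
# intensity normalisation
# ---------------------------------------------------------------------------

def zscore_normalize(v: Volume) -> Volume:
    """Per-slice z-score: subtract the slice mean, divide by its SD.

    Constant slices (background-only edge slices are common) become all-zero
    and a warning is logged rather than raising.
    """
    out = np.empty_like(v.data, dtype=np.float64)
    for k in range(v.shape[2]):
        sl = v.data[:, :, k].astype(np.float64)
        sd = sl.std()
        if sd == 0:
            log.warning("constant slice %d: z-score undefined, emitting zeros", k)
            out[:, :, k] = 0.0
        else:
            out[:, :, k] = (sl - sl.mean()) / sd
    return Volume(out, v.spacing, v.affine)


def minmax_rescale(v: Volume) -> Volume:
    """Affine rescale of the whole volume so min -> 0 and max -> 1."""
    data = v.data.astype(np.float64)
    lo, hi = data.min(), data.max()
    if hi == lo:
        log.warning("constant volume: min-max rescale undefined, emitting zeros")
        return Volume(np.zeros_like(data), v.spacing, v.affine)
    return Volume((data - lo) / (hi - lo), v.spacing, v.affine)


# ---------------------------------------------------------------------------
# bias field
# ---------------------------------------------------------------------------

def _poly_design(shape: tuple[int, int, int], order: int) -> np.ndarray:
    axes = [np.linspace(-1.0, 1.0, n) if n > 1 else np.zeros(n) for n in shape]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    coords = (X.ravel(), Y.ravel(), Z.ravel())
    cols = [np.ones(X.size)]
    for deg in range(1, order + 1):
        for combo in combinations_with_replacement(range(3), deg):
            term = np.ones(X.size)
            for ax in combo:
                term = term * coords[ax]
            cols.append(term)
    return np.column_stack(cols)


def estimate_bias_field(v: Volume, brain: BinaryMask, order: int = 3) -> Volume:
    """Estimate the smooth multiplicative intensity inhomogeneity field.

    Fits a low-order 3D polynomial to log-intensities inside the brain mask
    (least squares), exponentiates it over the whole grid, and normalises the
    field to mean 1 over the mask. The estimate is strictly positive by
    construction. Intensities that are not strictly positive inside the mask
    are shifted before the log.
    """
    if brain.shape != v.shape:
        raise ValueError("mask shape must match volume shape")
    m = brain.data.astype(bool).ravel()
    if not m.any():
        raise ValueError("brain mask is empty")
    vals = v.data.astype(np.float64).ravel()
    inside = vals[m]
    lo = inside.min()
    if lo <= 0:
        shift = -lo + 1e-3 * max(np.ptp(inside), 1.0)
        vals = vals + shift
        inside = inside + shift
    A = _poly_design(v.shape, order)
    Am = A[m]
    logi = np.log(inside)
    # robust fit: anatomy (lesions, residual tissue contrast) shows up as
    # heavy-tailed residuals against the smooth field; re-fit on inliers
    keep = np.ones(logi.size, dtype=bool)
    coef = None
    for _ in range(3):
        coef, *_ = np.linalg.lstsq(Am[keep], logi[keep], rcond=None)
        res = logi - Am @ coef
        res_in = res[keep]
        scale = 1.4826 * np.median(np.abs(res_in - np.median(res_in)))
        if scale <= 0:
            break
        new_keep = np.abs(res - np.median(res_in)) < 2.5 * scale
        if new_keep.sum() < max(A.shape[1] * 3, 16) or np.array_equal(new_keep, keep):
            break
        keep = new_keep
    field = np.exp(A @ coef).reshape(v.shape)
    field /= field.ravel()[m].mean()
    return Volume(field, v.spacing, v.affine)


def correct_bias(v: Volume, field: Volume) -> Volume:
    """Divide out a multiplicative bias field (field must be strictly positive)."""
    f = field.data.astype(np.float64)
    if f.min() <= 0:
        raise ValueError("bias field must be strictly positive")
    return Volume(v.data.astype(np.float64) / f, v.spacing, v.affine)


def apply_mask(v: Volume, brain: BinaryMask) -> Volume:
    """Zero every voxel outside the mask (skull-stripping by mask transfer)."""
    if brain.shape != v.shape:
        raise ValueError(f"shape mismatch: {v.shape} vs {brain.shape}")
    return _rewrap(v, v.data * (brain.data != 0))
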