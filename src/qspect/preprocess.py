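"""Lung segmentation, SPECT-to-CT registration and SPECT normalization.

The two modalities are fused by registering *binary lung masks* rather than
intensity volumes: segmenting the lungs independently in CT (Hounsfield
threshold) and in SPECT (count threshold) reduces the multimodal problem to
a unimodal one, so a plain mean-squared-error cost can drive an affine
registration without the premature-convergence pitfalls of
mutual-information metrics.

The registration itself is a multi-resolution quasi-Newton (L-BFGS) descent
of the MSE between Gaussian-smoothed masks, with analytic gradients and
centre-of-mass initialization; it is fully deterministic.

SPECT intensities are then normalized per scan to compensate for variations
in injected tracer activity. Two schemes are provided: min-max scaling to
[0, 1], and scaling by the 99th-percentile intensity, which is robust to
focal hotspot artifacts (a single very hot voxel inflates the maximum but
barely moves the 99th percentile).
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize
from skimage.morphology import ball

from .volume_io import Modality, Units, Volume3D

logger = logging.getLogger(__name__)

__all__ = [
    "BinaryMask3D",
    "AffineTransform3D",
    "NormalizationMode",
    "CT_LUNG_HU_RANGE",
    "SPECT_LUNG_THRESHOLD",
    "segment_lungs_ct",
    "segment_lungs_spect",
    "morphological_closing",
    "resize_spect_to_ct",
    "register_masks_affine",
    "apply_transform",
    "apply_transform_to_mask",
    "normalize_spect",
    "dice",
]

#: HU window selecting aerated lung parenchyma
CT_LUNG_HU_RANGE = (-950.0, -300.0)
#: counts above this are considered perfused lung tissue
SPECT_LUNG_THRESHOLD = 20.0
#: radius (voxels) of the spherical structuring element for mask closing
CLOSING_RADIUS = 5


@dataclass
class BinaryMask3D:
    """A boolean grid on the voxel lattice of a reference volume."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {self.values.shape}")

    @property
    def shape(self):
        return self.values.shape

    def count(self) -> int:
        return int(self.values.sum())


@dataclass
class AffineTransform3D:
    """Affine map in voxel units, (z, y, x) index order.

    Resampling convention: the transform maps points of the *fixed*
    (reference) grid into the *moving* volume, i.e.
    ``out(x) = moving(linear @ x + translation)``.
    """

    linear: np.ndarray  # 3x3
    translation: np.ndarray  # 3
    converged: bool = True

    def __post_init__(self) -> None:
        self.linear = np.asarray(self.linear, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if abs(np.linalg.det(self.linear)) < 1e-12:
            raise ValueError("affine linear part is singular")

    @classmethod
    def identity(cls) -> "AffineTransform3D":
        return cls(np.eye(3), np.zeros(3))

    def inverse(self) -> "AffineTransform3D":
        inv = np.linalg.inv(self.linear)
        return AffineTransform3D(inv, -inv @ self.translation, self.converged)

    def compose(self, other: "AffineTransform3D") -> "AffineTransform3D":
        """self after other: (self o other)(x) = self(other(x))."""
        return AffineTransform3D(
            self.linear @ other.linear,
            self.linear @ other.translation + self.translation,
        )


class NormalizationMode(str, enum.Enum):
    MAX = "max"
    PERCENTILE99 = "prct99"


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


def morphological_closing(mask: BinaryMask3D, radius: int = CLOSING_RADIUS) -> BinaryMask3D:
    """Binary closing with a discrete ball: dilation then erosion.

    Fills interior holes and concave boundary notches smaller than the ball.
    Extensive (output contains input) and idempotent.
    """
    if radius < 1:
        raise ValueError(f"radius must be >= 1, got {radius}")
    if not mask.values.any():
        return BinaryMask3D(mask.values.copy())
    selem = ball(radius)
    # pad so dilation at the border behaves as in an unbounded grid
    padded = np.pad(mask.values, radius, mode="constant")
    closed = ndimage.binary_erosion(
        ndimage.binary_dilation(padded, structure=selem), structure=selem
    )
    sl = tuple(slice(radius, -radius) for _ in range(3))
    return BinaryMask3D(closed[sl])


def _largest_component(mask: np.ndarray) -> np.ndarray:
    structure = np.ones((3, 3, 3), dtype=int)  # 26-connectivity
    comp, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return np.zeros_like(mask, dtype=bool)
    sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=np.arange(1, n + 1))
    return comp == (1 + int(np.argmax(sizes)))


def segment_lungs_ct(ct: Volume3D, closing_radius: int = CLOSING_RADIUS) -> BinaryMask3D:
    """Lung mask from CT: HU threshold, largest 3D component, closing.

    Voxels with HU in the closed interval [-950, -300] are selected, the
    largest 26-connected component is kept, and the result is closed with a
    ball of radius 5 voxels to fill vessels and interior holes.
    """
    if ct.modality is not Modality.CT:
        raise ValueError("segment_lungs_ct expects a CT volume")
    lo, hi = CT_LUNG_HU_RANGE
    in_range = (ct.values >= lo) & (ct.values <= hi)
    if not in_range.any():
        raise ValueError(f"no voxel in the lung HU range [{lo}, {hi}]: empty segmentation")
    largest = _largest_component(in_range)
    return morphological_closing(BinaryMask3D(largest), closing_radius)


def segment_lungs_spect(spect: Volume3D, threshold: float = SPECT_LUNG_THRESHOLD) -> BinaryMask3D:
    """Lung mask from SPECT counts: values strictly above the threshold (20)."""
    if spect.modality is not Modality.SPECT:
        raise ValueError("segment_lungs_spect expects a SPECT volume")
    return BinaryMask3D(spect.values > threshold)


# ---------------------------------------------------------------------------
# resampling and registration
# ---------------------------------------------------------------------------


def resize_spect_to_ct(spect: Volume3D, ct: Volume3D) -> Volume3D:
    """Trilinearly resample SPECT onto the CT grid shape.

    Axis endpoints are aligned (index i of the target maps to fractional
    index i*(n_src-1)/(n_tgt-1) of the source), so a 2-slice linear ramp
    upsampled to 4 slices interpolates exactly linearly.
    """
    src = spect.values
    tgt_shape = ct.shape
    if any(n < 2 for n in src.shape) or any(n < 2 for n in tgt_shape):
        raise ValueError(
            f"resize needs >= 2 voxels per axis (got SPECT {src.shape}, CT {tgt_shape})"
        )
    axes = [np.linspace(0, src.shape[k] - 1, tgt_shape[k]) for k in range(3)]
    grid = np.meshgrid(*axes, indexing="ij")
    resampled = ndimage.map_coordinates(src, np.stack(grid), order=1, mode="nearest")
    return Volume3D(resampled, ct.spacing, spect.modality, spect.units)


def register_masks_affine(
    moving: BinaryMask3D,
    fixed: BinaryMask3D,
    smoothing_sigma: float = 1.0,
    levels: tuple = ((4, 200), (2, 80), (1, 40)),
    param_scale: float = 10.0,
) -> AffineTransform3D:
    """Affine registration of two binary masks by mean-squared-error descent.

    Masks are converted to float, cropped to their joint bounding box and
    smoothed per pyramid level; the MSE between fixed and transformed moving
    is minimized by L-BFGS with analytic gradients, coarse to fine
    (``levels`` is a sequence of (downsampling factor, max iterations)).
    Initialization aligns centres of mass. Deterministic given inputs.

    Returns the transform that resamples the moving mask onto the fixed
    grid. If the finest level stops at its iteration cap a warning is
    emitted and the best-found transform is returned with
    ``converged=False``.
    """
    if not moving.values.any() or not fixed.values.any():
        raise ValueError("cannot register an empty mask")
    if moving.shape != fixed.shape:
        raise ValueError(f"mask shapes differ: {moving.shape} vs {fixed.shape}")

    both = fixed.values | moving.values
    idx = np.argwhere(both)
    lo = np.maximum(idx.min(0) - 8, 0)
    hi = np.minimum(idx.max(0) + 9, both.shape)
    sl = tuple(slice(int(l), int(h)) for l, h in zip(lo, hi))
    f_crop = fixed.values[sl].astype(float)
    m_crop = moving.values[sl].astype(float)

    cf = np.array(ndimage.center_of_mass(f_crop))
    cm = np.array(ndimage.center_of_mass(m_crop))
    A = np.eye(3)
    t = cm - cf
    r = param_scale
    converged = True
    for s, maxiter in levels:
        f = ndimage.gaussian_filter(f_crop, smoothing_sigma * s)[::s, ::s, ::s]
        m = ndimage.gaussian_filter(m_crop, smoothing_sigma * s)[::s, ::s, ::s]
        grad_m = np.array(np.gradient(m))
        grid = np.indices(f.shape).reshape(3, -1).astype(float)
        f_flat = f.ravel()
        n_vox = f_flat.size

        def cost_grad(params):
            a = np.eye(3) + params[:9].reshape(3, 3) / r
            tr = params[9:]
            y = a @ grid + tr[:, None]
            mv = ndimage.map_coordinates(m, y, order=1, mode="constant", cval=0.0)
            d = mv - f_flat
            g = np.stack(
                [ndimage.map_coordinates(grad_m[k], y, order=1, mode="constant", cval=0.0) for k in range(3)]
            )
            grad_t = 2.0 / n_vox * (g @ d)
            grad_a = 2.0 / n_vox * np.einsum("in,n,kn->ik", g, d, grid)
            return float(np.mean(d**2)), np.concatenate([grad_a.ravel() / r, grad_t])

        x0 = np.concatenate([(A - np.eye(3)).ravel() * r, t / s])
        res = optimize.minimize(
            cost_grad,
            x0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-14, "gtol": 1e-11},
        )
        A = np.eye(3) + res.x[:9].reshape(3, 3) / r
        t = res.x[9:] * s
        if s == 1 and res.status == 1:  # finest level hit the iteration cap
            converged = False
            warnings.warn(
                "mask registration stopped at the fine-level iteration cap; "
                "returning best transform found",
                RuntimeWarning,
            )
    # re-express in the uncropped frame: y_full = A (x_full - lo) + t + lo
    offset = lo.astype(float)
    t_full = t + offset - A @ offset
    return AffineTransform3D(A, t_full, converged=converged)


def apply_transform(
    volume: Volume3D,
    transform: AffineTransform3D,
    reference: Volume3D,
    interpolation: str = "linear",
) -> Volume3D:
    """Resample a volume through an affine onto the reference grid.

    Trilinear interpolation; voxels mapping outside the source field of
    view are set to 0.
    """
    order = 1 if interpolation == "linear" else 0
    out = ndimage.affine_transform(
        volume.values,
        transform.linear,
        offset=transform.translation,
        output_shape=reference.shape,
        order=order,
        mode="constant",
        cval=0.0,
    )
    return Volume3D(out, reference.spacing, volume.modality, volume.units)


def apply_transform_to_mask(
    mask: BinaryMask3D, transform: AffineTransform3D, reference_shape: tuple[int, int, int]
) -> BinaryMask3D:
    """Resample a binary mask through an affine (linear interp, 0.5 cut)."""
    out = ndimage.affine_transform(
        mask.values.astype(float),
        transform.linear,
        offset=transform.translation,
        output_shape=tuple(int(n) for n in reference_shape),
        order=1,
        mode="constant",
        cval=0.0,
    )
    return BinaryMask3D(out >= 0.5)


def dice(a: BinaryMask3D, b: BinaryMask3D) -> float:
    """Dice overlap coefficient of two masks."""
    inter = np.logical_and(a.values, b.values).sum()
    denom = a.values.sum() + b.values.sum()
    if denom == 0:
        return 1.0
    return 2.0 * inter / denom


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def normalize_spect(
    spect: Volume3D,
    mode: NormalizationMode | str,
    statistics_mask: BinaryMask3D | None = None,
) -> Volume3D:
    """Normalize SPECT intensities per scan.

    MAX mode: (v - min) / (max - min), output exactly in [0, 1].

    PERCENTILE99 mode: (v - min) / (p99 - min) where p99 is the 99th
    percentile (linear interpolation between order statistics); the voxel
    at the 99th percentile maps to exactly 1.0 and hotter voxels exceed 1 —
    deliberately unclipped.

    Statistics are taken over the whole volume by default (the per-scan
    convention); pass ``statistics_mask`` (e.g. the lung mask) to restrict
    them.
    """
    mode = NormalizationMode(mode)
    v = spect.values
    stats_values = v if statistics_mask is None else v[statistics_mask.values]
    if stats_values.size == 0:
        raise ValueError("statistics mask is empty")
    vmin = float(stats_values.min())
    if mode is NormalizationMode.MAX:
        denom = float(stats_values.max()) - vmin
    else:
        denom = float(np.percentile(stats_values, 99)) - vmin
    if denom <= 0:
        raise ValueError(
            f"cannot normalize: denominator {denom} (constant or degenerate volume)"
        )
    out = (v - vmin) / denom
    return Volume3D(out, spect.spacing, spect.modality, Units.NORMALIZED)
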