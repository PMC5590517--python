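"""Landmark-guided nonlinear co-registration of histology onto MRI.

The deformation family is the 2-D thin-plate spline (TPS): an affine part
plus radial-basis coefficients with kernel ``U(r) = r^2 log r``, solved
from the standard augmented linear system.  With regularization
``lambda = 0`` the warp interpolates the landmarks exactly; increasing
``lambda`` trades landmark fidelity for smoothness.  The exact inverse of
a TPS has no closed form, so the inverse is approximated by refitting with
source and target landmarks swapped.

Registration quality is scored by the Dice coefficient between the warped
histology tissue outline and the MRI outline; :func:`register_with_qc`
picks the regularization value that maximizes it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .grids import RegularGrid
from .histology import PatchMap

__all__ = [
    "LandmarkSet",
    "ThinPlateSplineWarp",
    "fit_warp",
    "apply_warp",
    "dice",
    "extract_outline",
    "register_with_qc",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LandmarkSet:
    """Paired 2-D points: ``source`` in the histology mm frame, ``target``
    in the MRI mm frame."""

    source: np.ndarray
    target: np.ndarray

    def __post_init__(self):
        src = np.atleast_2d(np.asarray(self.source, dtype=float))
        dst = np.atleast_2d(np.asarray(self.target, dtype=float))
        if src.shape != dst.shape or src.shape[1] != 2:
            raise ValueError("source and target must both be (n, 2) arrays")
        if src.shape[0] < 4:
            raise ValueError("at least 4 landmark pairs are required")
        if not (np.isfinite(src).all() and np.isfinite(dst).all()):
            raise ValueError("landmark coordinates must be finite")
        d = np.linalg.norm(src[:, None] - src[None], axis=-1)
        np.fill_diagonal(d, np.inf)
        dup = np.argwhere(d < 1e-12)
        if dup.size:
            i, j = dup[0]
            raise ValueError(f"duplicate source landmarks at rows {i} and {j}")
        centered = src - src.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, d[np.isfinite(d)].max())) < 2:
            raise ValueError("source landmarks are collinear; affine part is ill-posed")
        object.__setattr__(self, "source", src)
        object.__setattr__(self, "target", dst)

    def __len__(self):
        return self.source.shape[0]

    def swapped(self):
        return LandmarkSet(self.target, self.source)


def _tps_kernel(r2):
    # U(r) = r^2 log r = 0.5 * r^2 log r^2, with U(0) = 0
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 0.5 * r2 * np.log(r2)
    return np.where(r2 > 0, out, 0.0)


@dataclass(frozen=True)
class ThinPlateSplineWarp:
    """Forward TPS mapping (source mm -> target mm)."""

    landmarks: LandmarkSet
    regularization: float
    coef: np.ndarray  # (n + 3, 2): kernel weights then [1, x, y] affine part

    def transform(self, points):
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        src = self.landmarks.source
        r2 = np.sum((pts[:, None] - src[None]) ** 2, axis=-1)
        K = _tps_kernel(r2)
        P = np.column_stack([np.ones(len(pts)), pts])
        return K @ self.coef[:-3] + P @ self.coef[-3:]

    def inverse(self):
        """Approximate inverse by refitting with swapped landmarks."""
        return fit_warp(self.landmarks.swapped(), self.regularization)


def fit_warp(landmarks: LandmarkSet, regularization: float = 0.0):
    """Solve the augmented TPS system; ``regularization >= 0`` adds
    ``lambda I`` to the kernel block (0 interpolates exactly)."""
    if regularization < 0:
        raise ValueError("regularization must be non-negative")
    src, dst = landmarks.source, landmarks.target
    n = len(landmarks)
    r2 = np.sum((src[:, None] - src[None]) ** 2, axis=-1)
    K = _tps_kernel(r2) + regularization * np.eye(n)
    P = np.column_stack([np.ones(n), src])
    A = np.zeros((n + 3, n + 3))
    A[:n, :n] = K
    A[:n, n:] = P
    A[n:, :n] = P.T
    b = np.zeros((n + 3, 2))
    b[:n] = dst
    coef = np.linalg.solve(A, b)
    return ThinPlateSplineWarp(landmarks, regularization, coef)


def apply_warp(patch_map: PatchMap, warp: ThinPlateSplineWarp, target_grid: RegularGrid,
               method: str = "linear"):
    """Resample a source-frame map onto ``target_grid`` through the warp.

    Pull-back resampling: each target pixel center is mapped through the
    *inverse* warp (landmark-swap refit) into the source frame and the map
    is interpolated there — bilinearly for metric maps, nearest-neighbour
    for masks/labels.  Pixels mapping outside the source domain, or onto
    invalid source patches, are invalid in the output.
    """
    from scipy.ndimage import map_coordinates

    if method not in ("linear", "nearest"):
        raise ValueError("method must be 'linear' or 'nearest'")
    inv = warp.inverse()
    t0, t1 = target_grid.pixel_centers()
    pts = np.column_stack([t0.ravel(), t1.ravel()])
    src_pts = inv.transform(pts)
    i0, i1 = patch_map.grid.to_index(src_pts[:, 0], src_pts[:, 1])
    coords = np.vstack([i0, i1])
    order = 1 if method == "linear" else 0

    values = np.where(patch_map.valid, patch_map.values, 0.0).astype(float)
    num = map_coordinates(values, coords, order=order, mode="nearest")
    wgt = map_coordinates(patch_map.valid.astype(float), coords, order=order,
                          mode="nearest")
    n0, n1 = patch_map.grid.shape
    inside = (i0 >= -0.5) & (i0 <= n0 - 0.5) & (i1 >= -0.5) & (i1 <= n1 - 0.5)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / wgt
    valid = inside & (wgt > 0.5)
    out[~valid] = np.nan
    shape = target_grid.shape
    return PatchMap(out.reshape(shape), valid.reshape(shape),
                    np.ones(shape, dtype=int), target_grid, name=patch_map.name)


def dice(a, b):
    """Dice overlap ``2|a & b| / (|a| + |b|)`` of two same-shape masks.

    Returns 0 (with a log notice) when both masks are empty.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = a.sum() + b.sum()
    if denom == 0:
        log.info("dice: both masks empty; returning 0 by convention")
        return 0.0
    return 2.0 * np.logical_and(a, b).sum() / denom


def extract_outline(image, grid: RegularGrid | None = None):
    """Tissue outline mask: Otsu threshold (dark tissue on bright
    background, or the reverse — the side with the larger foreground is
    discarded as background), largest connected component, holes filled."""
    from scipy.ndimage import binary_fill_holes, label as cc_label
    from skimage.filters import threshold_otsu

    img = np.asarray(image, dtype=float)
    t = threshold_otsu(img)
    fg = img < t
    if fg.mean() > 0.5:
        fg = ~fg
    lab, n = cc_label(fg)
    if n == 0:
        return np.zeros_like(fg)
    sizes = np.bincount(lab.ravel())[1:]
    keep = lab == (np.argmax(sizes) + 1)
    return binary_fill_holes(keep)


def register_with_qc(histo_outline, mri_outline, landmarks: LandmarkSet,
                     lambda_grid=(0.0, 0.001, 0.01, 0.1), histo_grid=None,
                     mri_grid=None, dice_floor=0.5):
    """Fit TPS warps across a regularization grid and keep the one that
    maximizes the Dice overlap of the warped histology outline with the
    MRI outline.

    ``histo_outline``/``mri_outline`` are boolean masks on ``histo_grid``
    and ``mri_grid`` (:class:`RegularGrid`).  Returns ``(warp, dice_score,
    ok_flag)``; ``ok_flag`` is False when every candidate scores below
    ``dice_floor``.
    """
    histo_outline = np.asarray(histo_outline, dtype=bool)
    mri_outline = np.asarray(mri_outline, dtype=bool)
    if not histo_outline.any():
        raise ValueError("histology outline is empty")
    if histo_grid is None or mri_grid is None:
        raise ValueError("histo_grid and mri_grid are required")
    src_map = PatchMap(histo_outline.astype(float), np.ones_like(histo_outline),
                       np.ones(histo_outline.shape, dtype=int), histo_grid, "outline")
    best = (None, -1.0)
    for lam in lambda_grid:
        warp = fit_warp(landmarks, lam)
        warped = apply_warp(src_map, warp, mri_grid, method="nearest")
        mask = warped.valid & (np.nan_to_num(warped.values) > 0.5)
        score = dice(mask, mri_outline)
        if score > best[1]:
            best = (warp, score)
    warp, score = best
    ok = score >= dice_floor
    if not ok:
        log.warning("register_with_qc: best Dice %.3f below floor %.3f", score,
                    dice_floor)
    return warp, score, ok
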