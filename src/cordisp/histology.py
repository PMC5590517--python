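"""Quantitative analysis of histology-like images.

Pipeline per stained section:

* **Palmgren-style fiber images** — neurites are segmented by k-means on
  intensity (darkest cluster of 4), their local orientation estimated by
  structure-tensor analysis (derivative-of-Gaussian gradients, Gaussian
  tensor smoothing), and orientation dispersion summarized per patch as the
  coherence-weighted axial circular variance ``CV = 1 - Rbar`` of the
  doubled angles.
* **Immunostain images** — stained material is segmented by k-means on
  intensity (darkest cluster of 3) and summarized per patch as the stained
  area fraction of tissue.

Patches tile the physical frame at the MRI in-plane resolution
(0.16 x 0.20 mm^2 by default) so patch maps land on the MRI grid after
co-registration.

Conventions: image arrays are indexed ``[i, j]`` with axis 0 along physical
x and axis 1 along physical y; orientations ``theta`` are axial angles in
``[0, pi)`` measured from the +x axis toward +y (i.e. along axis 0 toward
axis 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.cluster import KMeans

from .grids import RegularGrid

__all__ = [
    "HistologyImage",
    "OrientationField",
    "PatchMap",
    "make_patch_grid",
    "structure_tensor_orientations",
    "segment_neurites",
    "segment_stain",
    "patch_circular_variance",
    "patch_staining_fraction",
]

DEFAULT_PIXEL_UM = 1.008
DEFAULT_PATCH_MM = (0.16, 0.20)


@dataclass
class HistologyImage:
    """2-D grayscale intensity image with physical pixel size in microns."""

    data: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_UM
    tissue_mask: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 2:
            raise ValueError("image must be 2-D grayscale")
        if not np.isfinite(self.data).all():
            raise ValueError("image intensities must be finite")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")
        if self.tissue_mask is not None:
            self.tissue_mask = np.asarray(self.tissue_mask, dtype=bool)
            if self.tissue_mask.shape != self.data.shape:
                raise ValueError("tissue mask shape mismatch")

    @property
    def grid(self):
        p = self.pixel_size_um * 1e-3
        return RegularGrid(self.data.shape, (p, p))


@dataclass
class OrientationField:
    """Per-pixel axial orientation with confidence weights.

    ``theta`` is defined only where ``weight > 0``; ``neurite_mask`` limits
    which pixels enter patch statistics.
    """

    theta: np.ndarray
    weight: np.ndarray
    neurite_mask: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_UM


@dataclass
class PatchMap:
    """Patch-resolution metric map with validity mask and pixel counts."""

    values: np.ndarray
    valid: np.ndarray
    counts: np.ndarray
    grid: RegularGrid
    name: str = ""


def make_patch_grid(image: HistologyImage, patch_mm=DEFAULT_PATCH_MM, origin_mm=(0.0, 0.0)):
    """Patch grid covering ``image`` with patches of physical size
    ``patch_mm`` tiled from ``origin_mm``."""
    ext0, ext1 = image.grid.extent_mm
    n0 = int(np.ceil((ext0 - 1e-9) / patch_mm[0]))
    n1 = int(np.ceil((ext1 - 1e-9) / patch_mm[1]))
    return RegularGrid((n0, n1), tuple(patch_mm), tuple(origin_mm))


def structure_tensor_orientations(
    img: HistologyImage,
    sigma_d_um: float = 1.0,
    sigma_s_um: float = 4.0,
    neurite_mask: np.ndarray | None = None,
    energy_eps: float = 1e-3,
):
    """Per-pixel along-structure orientation and coherence weight.

    Gradients use derivative-of-Gaussian kernels of spread ``sigma_d_um``;
    the tensor components are then smoothed with a Gaussian of spread
    ``sigma_s_um``.  The orientation is that of the eigenvector with the
    *smaller* eigenvalue (along the local structure); the weight is the
    coherence ``(l1 - l2)/(l1 + l2)``, zeroed where the tensor energy falls
    below ``energy_eps`` times its maximum.
    """
    if img.data.shape[0] < 3 or img.data.shape[1] < 3:
        raise ValueError("image must be at least 3 x 3 pixels")
    px = img.pixel_size_um
    if sigma_d_um < px / 2 or sigma_s_um < px / 2:
        raise ValueError(
            f"Gaussian spread below half a pixel ({px/2:.3g} um) is unresolvable"
        )
    sd = sigma_d_um / px
    ss = sigma_s_um / px
    data = img.data.astype(np.float32)
    g0 = ndimage.gaussian_filter(data, sd, order=(1, 0), mode="nearest")
    g1 = ndimage.gaussian_filter(data, sd, order=(0, 1), mode="nearest")
    j00 = ndimage.gaussian_filter(g0 * g0, ss, mode="nearest")
    j11 = ndimage.gaussian_filter(g1 * g1, ss, mode="nearest")
    j01 = ndimage.gaussian_filter(g0 * g1, ss, mode="nearest")

    energy = j00 + j11
    # dominant-gradient angle, then +pi/2 for the along-structure direction
    alpha = 0.5 * np.arctan2(2.0 * j01, j00 - j11)
    theta = np.mod(alpha + np.pi / 2.0, np.pi)
    with np.errstate(invalid="ignore", divide="ignore"):
        coherence = np.sqrt((j00 - j11) ** 2 + 4.0 * j01**2) / energy
    weight = np.where(energy >= energy_eps * energy.max(), coherence, 0.0)
    weight = np.nan_to_num(weight, nan=0.0)
    if neurite_mask is None:
        neurite_mask = weight > 0
    return OrientationField(theta, weight.astype(np.float32), neurite_mask, px)


def _kmeans_darkest(
    data, tissue_mask, k, seed, n_init, sample_max, what
):
    vals = data[tissue_mask] if tissue_mask is not None else data.ravel()
    if vals.size == 0:
        warnings.warn(f"{what}: empty tissue mask; returning empty mask")
        return np.zeros(data.shape, dtype=bool)
    lo, hi = float(vals.min()), float(vals.max())
    if hi - lo < 1e-6 * max(1.0, abs(hi)):
        # constant tissue: decide stained vs unstained against the
        # out-of-mask background (stained material is dark at high contrast)
        if tissue_mask is not None and not tissue_mask.all():
            background = float(np.mean(data[~tissue_mask]))
            if hi <= 0.5 * background:
                warnings.warn(
                    f"{what}: uniformly dark tissue; returning full mask"
                )
                return tissue_mask.copy()
        warnings.warn(f"{what}: degenerate constant image; returning empty mask")
        return np.zeros(data.shape, dtype=bool)
    rng = np.random.default_rng(seed)
    fit_vals = vals
    if vals.size > sample_max:
        fit_vals = rng.choice(vals, size=sample_max, replace=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # duplicate-cluster warnings on 2-tone data
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        km.fit(fit_vals.reshape(-1, 1).astype(np.float64))
    centers = np.sort(km.cluster_centers_.ravel())
    # collapse numerically duplicate centroids (few-tone images)
    distinct = centers[np.concatenate([[True], np.diff(centers) > 1e-9 * (hi - lo)])]
    threshold = 0.5 * (distinct[0] + distinct[1])
    mask = data <= threshold
    if tissue_mask is not None:
        mask &= tissue_mask
    return mask


def segment_neurites(img: HistologyImage, k: int = 4, seed: int = 0, n_init: int = 20,
                     sample_max: int = 200_000):
    """Darkest-of-``k`` k-means intensity segmentation of neurites
    (silver-stained material is darkest).  Deterministic given ``seed``."""
    if k < 2:
        raise ValueError("k must be at least 2")
    return _kmeans_darkest(
        img.data, img.tissue_mask, k, seed, n_init, sample_max, "segment_neurites"
    )


def segment_stain(img: HistologyImage, k: int = 3, seed: int = 0, n_init: int = 20,
                  sample_max: int = 200_000):
    """Darkest-of-``k`` k-means segmentation of immunostained material."""
    if k < 2:
        raise ValueError("k must be at least 2")
    return _kmeans_darkest(
        img.data, img.tissue_mask, k, seed, n_init, sample_max, "segment_stain"
    )


def _patch_ids(shape, pixel_mm, grid: RegularGrid):
    """Flat patch id per pixel (-1 outside the grid), assigned by center."""
    i0 = np.floor(
        ((np.arange(shape[0]) + 0.5) * pixel_mm - grid.origin_mm[0]) / grid.spacing_mm[0]
    ).astype(int)
    i1 = np.floor(
        ((np.arange(shape[1]) + 0.5) * pixel_mm - grid.origin_mm[1]) / grid.spacing_mm[1]
    ).astype(int)
    ok0 = (i0 >= 0) & (i0 < grid.shape[0])
    ok1 = (i1 >= 0) & (i1 < grid.shape[1])
    ids = i0[:, None] * grid.shape[1] + i1[None, :]
    ids[~ok0, :] = -1
    ids[:, ~ok1] = -1
    return ids


def patch_circular_variance(
    field: OrientationField,
    grid: RegularGrid,
    min_pixels: int = 50,
    tissue_mask: np.ndarray | None = None,
    min_tissue_fraction: float = 0.5,
):
    """Patch-wise weighted axial circular variance of neurite orientations.

    Per patch, over neurite pixels with positive weight:
    ``Rbar = |sum_j w_j (cos 2 theta_j, sin 2 theta_j)| / sum_j w_j`` and
    ``CV = 1 - Rbar``.  Patches with fewer than ``min_pixels`` contributing
    pixels (or, when a tissue mask is given, tissue coverage below
    ``min_tissue_fraction``) are masked invalid.
    """
    if grid.shape[0] < 1 or grid.shape[1] < 1:
        raise ValueError("patch grid is empty")
    pixel_mm = field.pixel_size_um * 1e-3
    ids = _patch_ids(field.theta.shape, pixel_mm, grid)
    use = (field.weight > 0) & field.neurite_mask & (ids >= 0)
    n_patches = grid.shape[0] * grid.shape[1]
    flat = ids[use]
    w = field.weight[use].astype(np.float64)
    th2 = 2.0 * field.theta[use]
    sum_w = np.bincount(flat, weights=w, minlength=n_patches)
    sum_c = np.bincount(flat, weights=w * np.cos(th2), minlength=n_patches)
    sum_s = np.bincount(flat, weights=w * np.sin(th2), minlength=n_patches)
    counts = np.bincount(flat, minlength=n_patches)
    with np.errstate(invalid="ignore", divide="ignore"):
        rbar = np.hypot(sum_c, sum_s) / sum_w
    cv = np.clip(1.0 - rbar, 0.0, 1.0)
    valid = counts >= min_pixels
    if tissue_mask is not None:
        inside = ids >= 0
        tiss = np.bincount(ids[inside], weights=tissue_mask[inside].astype(float),
                           minlength=n_patches)
        tot = np.bincount(ids[inside], minlength=n_patches)
        with np.errstate(invalid="ignore", divide="ignore"):
            valid &= (tiss / np.maximum(tot, 1)) >= min_tissue_fraction
    shape = grid.shape
    return PatchMap(
        np.where(valid, cv, np.nan).reshape(shape),
        valid.reshape(shape),
        counts.reshape(shape),
        grid,
        name="CV",
    )


def patch_staining_fraction(
    stain_mask: np.ndarray,
    grid: RegularGrid,
    pixel_size_um: float = DEFAULT_PIXEL_UM,
    tissue_mask: np.ndarray | None = None,
    min_tissue_fraction: float = 0.5,
    name: str = "",
):
    """Patch-wise stained-area fraction of tissue, in [0, 1].

    Patches without tissue (or with coverage below ``min_tissue_fraction``)
    are masked invalid.
    """
    if grid.shape[0] < 1 or grid.shape[1] < 1:
        raise ValueError("patch grid is empty")
    stain_mask = np.asarray(stain_mask, dtype=bool)
    if tissue_mask is None:
        tissue_mask = np.ones_like(stain_mask)
    pixel_mm = pixel_size_um * 1e-3
    ids = _patch_ids(stain_mask.shape, pixel_mm, grid)
    inside = ids >= 0
    n_patches = grid.shape[0] * grid.shape[1]
    flat = ids[inside]
    tiss = np.bincount(flat, weights=tissue_mask[inside].astype(float), minlength=n_patches)
    stained = np.bincount(
        flat, weights=(stain_mask & tissue_mask)[inside].astype(float), minlength=n_patches
    )
    tot = np.bincount(flat, minlength=n_patches)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = stained / tiss
        coverage = tiss / np.maximum(tot, 1)
    valid = (tiss > 0) & (coverage >= min_tissue_fraction)
    shape = grid.shape
    return PatchMap(
        np.where(valid, frac, np.nan).reshape(shape),
        valid.reshape(shape),
        tiss.astype(int).reshape(shape),
        grid,
        name=name,
    )
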