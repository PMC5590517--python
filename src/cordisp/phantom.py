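"""Synthetic spinal-cord specimen with known microstructural ground truth.

A phantom is a sagittal cord slab on the MRI in-plane grid (default 64 x 64
voxels of 0.16 x 0.20 mm^2) containing gray matter, white matter and —
for the "MS" variant — focal demyelinated lesions in each.  Every tissue
region carries ground-truth microstructure (orientation dispersion ODI,
neurite density NDI, free-water fraction IVF, restricted "dot" fraction,
dominant fiber axis) and per-stain staining fractions.  Regions are
subdivided into regions-of-interest along the cord axis; each ROI receives
mild multiplicative jitter of the regional truth so that ROI-level
statistics have genuine between-ROI variance.

From the ground truth the module generates the three data streams of an
MRI-histology validation experiment:

* a noisy multi-shell diffusion-weighted volume (Rician noise, forward
  model from :mod:`cordisp.noddi`),
* silver-staining-like fiber images: dark strokes whose axial orientations
  follow a circular Watson distribution matched to the regional ODI and
  whose density scales with NDI,
* immunostain-like images: dark blobs from a seeded Boolean disk process
  whose expected covered-area fraction per ROI equals the ROI's true
  staining fraction.

Lesions are constructed with *lower* dispersion and myelin than matched
nonlesional tissue, and gray matter with higher dispersion than white —
the contrasts the downstream analysis is designed to detect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
import shapely.affinity
from shapely.geometry import Point, box

from .containers import DwiVolume
from .grids import RegularGrid
from .histology import HistologyImage
from .noddi import NoddiParams, noddi_signal
from .protocol import AcquisitionProtocol, default_protocol  # noqa: F401
from .watson import kappa_from_odi, sample_axial_angles

__all__ = [
    "STAINS",
    "TISSUE_LABELS",
    "TissueRegion",
    "PhantomSpec",
    "GroundTruthMaps",
    "default_phantom_spec",
    "make_phantom",
    "simulate_dwi",
    "simulate_fiber_image",
    "simulate_stain_image",
]

STAINS = ("MSF", "NSF", "ASF", "uGSF")
TISSUE_LABELS = {"WM": 1, "GM": 2, "WM_lesion": 3, "GM_lesion": 4}

#: fraction of a stroke's nominal footprint relative to neurite density
_STROKE_COVERAGE_PER_NDI = 0.45
#: stain blob radius in pixels of the histology grid
_BLOB_RADIUS_PX = 3


@dataclass
class TissueRegion:
    """One tissue compartment: geometry (shapely, physical mm, (x, y))
    plus its ground-truth microstructure and staining fractions."""

    label: str
    geometry: shapely.Geometry
    odi_true: float
    ndi_true: float
    ivf_true: float
    dot_true: float
    mu_angle_deg: float
    stain_fraction_true: dict
    n_rois: int = 1
    jitter_rel: float = 0.10
    jitter_mu_deg: float = 4.0

    def __post_init__(self):
        if self.label not in TISSUE_LABELS:
            raise ValueError(f"unknown tissue label {self.label!r}")
        for name in ("odi_true", "ndi_true", "ivf_true", "dot_true"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 < self.odi_true < 1.0:
            raise ValueError("odi_true must lie strictly in (0, 1)")
        missing = set(STAINS) - set(self.stain_fraction_true)
        if missing:
            raise ValueError(f"missing stain fractions: {sorted(missing)}")
        for s, v in self.stain_fraction_true.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"stain fraction {s} must lie in [0, 1]")
        if not 0.0 <= self.mu_angle_deg < 180.0:
            raise ValueError("mu_angle_deg must lie in [0, 180)")
        if self.n_rois < 1:
            raise ValueError("n_rois must be >= 1")


@dataclass
class PhantomSpec:
    """Full phantom description; deterministic given ``seed``."""

    regions: list
    grid_shape: tuple = (64, 64)
    voxel_size_mm: tuple = (0.16, 0.20)
    histo_pixel_um: float = 1.008
    snr_b0: float = 30.0
    seed: int = 0

    def __post_init__(self):
        if len(self.grid_shape) != 2 or min(self.grid_shape) < 1:
            raise ValueError("grid_shape must be a positive integer pair")
        if min(self.voxel_size_mm) <= 0 or self.histo_pixel_um <= 0:
            raise ValueError("voxel and pixel sizes must be positive")
        if not self.snr_b0 > 0:
            raise ValueError("snr_b0 must be positive (may be inf)")
        ext = self.extent_mm
        frame = box(0.0, 0.0, ext[0], ext[1])
        for r in self.regions:
            if not frame.buffer(1e-6).contains(r.geometry):
                raise ValueError(f"region {r.label!r} extends outside the grid")

    @property
    def extent_mm(self):
        return (
            self.grid_shape[0] * self.voxel_size_mm[0],
            self.grid_shape[1] * self.voxel_size_mm[1],
        )

    @property
    def mri_grid(self):
        return RegularGrid(tuple(self.grid_shape), tuple(self.voxel_size_mm))

    @property
    def histo_grid(self):
        p = self.histo_pixel_um * 1e-3
        ext = self.extent_mm
        return RegularGrid((int(round(ext[0] / p)), int(round(ext[1] / p))), (p, p))


def _ellipse(cx, cy, rx, ry):
    return shapely.affinity.scale(Point(cx, cy).buffer(1.0, quad_segs=64), rx, ry)


def _region_params(label, **overrides):
    """Literature-guided regional ground truth for the default phantom."""
    base = {
        "WM": dict(
            odi_true=0.10, ndi_true=0.65, ivf_true=0.05, dot_true=0.10,
            stain_fraction_true=dict(MSF=0.55, NSF=0.35, ASF=0.25, uGSF=0.15),
        ),
        "GM": dict(
            odi_true=0.45, ndi_true=0.45, ivf_true=0.07, dot_true=0.12,
            stain_fraction_true=dict(MSF=0.30, NSF=0.30, ASF=0.20, uGSF=0.15),
        ),
        "WM_lesion": dict(
            odi_true=0.06, ndi_true=0.30, ivf_true=0.18, dot_true=0.08,
            stain_fraction_true=dict(MSF=0.10, NSF=0.20, ASF=0.35, uGSF=0.10),
        ),
        "GM_lesion": dict(
            odi_true=0.28, ndi_true=0.25, ivf_true=0.20, dot_true=0.08,
            stain_fraction_true=dict(MSF=0.08, NSF=0.18, ASF=0.22, uGSF=0.10),
        ),
    }[label]
    base.update(overrides)
    return base


def default_phantom_spec(kind="ms", seed=0, grid_shape=(64, 64), histo_pixel_um=4.0,
                         snr_b0=30.0):
    """Default sagittal-cord phantom.

    ``kind="control"`` builds gray + white matter only (20 ROIs);
    ``kind="ms"`` adds four focal lesions in each of white and gray matter
    (28 ROIs), with lower dispersion and myelin inside lesions.  All region
    geometries are constructed disjoint (lesions are punched out of their
    parent tissue).

    The default histology pixel here is 4 um: the generator draws strokes a
    few pixels wide, and 4 um keeps full-slab fiber images at a tractable
    size; pass ``histo_pixel_um=1.008`` for scanner-resolution patches of
    smaller extent.
    """
    spec_probe = PhantomSpec([], grid_shape=grid_shape, histo_pixel_um=histo_pixel_um,
                             snr_b0=snr_b0, seed=seed)
    ex, ey = spec_probe.extent_mm
    cx, cy = ex / 2, ey / 2
    cord = _ellipse(cx, cy, 0.25 * ex, 0.45 * ey)
    gm = _ellipse(cx, cy, 0.088 * ex, 0.36 * ey)
    mu = 90.0  # cord axis along physical y

    regions = []
    if kind == "control":
        regions.append(TissueRegion("GM", gm, mu_angle_deg=mu, n_rois=10,
                                    **_region_params("GM")))
        regions.append(TissueRegion("WM", cord.difference(gm), mu_angle_deg=mu,
                                    n_rois=10, **_region_params("WM")))
    elif kind == "ms":
        wm_les = [
            _ellipse(cx - 0.13 * ex, cy + dy * ey, 0.04 * ex, 0.045 * ey)
            for dy in (-0.28, -0.10, 0.10, 0.28)
        ]
        gm_les = [
            _ellipse(cx, cy + dy * ey, 0.035 * ex, 0.04 * ey)
            for dy in (-0.24, -0.08, 0.08, 0.24)
        ]
        gm_geom = gm.difference(shapely.unary_union(gm_les))
        wm_geom = cord.difference(gm).difference(shapely.unary_union(wm_les))
        regions.append(TissueRegion("GM", gm_geom, mu_angle_deg=mu, n_rois=10,
                                    **_region_params("GM")))
        regions.append(TissueRegion("WM", wm_geom, mu_angle_deg=mu, n_rois=10,
                                    **_region_params("WM")))
        for g in wm_les:
            regions.append(TissueRegion("WM_lesion", g, mu_angle_deg=mu,
                                        **_region_params("WM_lesion")))
        for g in gm_les:
            regions.append(TissueRegion("GM_lesion", g, mu_angle_deg=mu,
                                        **_region_params("GM_lesion")))
    else:
        raise ValueError("kind must be 'control' or 'ms'")
    return PhantomSpec(regions, grid_shape=grid_shape, histo_pixel_um=histo_pixel_um,
                       snr_b0=snr_b0, seed=seed)


@dataclass
class GroundTruthMaps:
    """Rasterized phantom: label/ROI maps on both grids, an ROI table of
    jittered true values, and per-voxel truth maps on the MRI grid."""

    spec: PhantomSpec
    mri_grid: RegularGrid
    histo_grid: RegularGrid
    label_mri: np.ndarray
    roi_mri: np.ndarray
    label_histo: np.ndarray
    roi_histo: np.ndarray
    roi_table: pd.DataFrame

    def truth_map(self, column):
        """Per-voxel MRI-grid map of an ROI-table column (NaN outside)."""
        if column not in self.roi_table.columns:
            raise KeyError(f"no ground-truth column {column!r}")
        lut = np.full(int(self.roi_table["roi_id"].max()) + 1, np.nan)
        lut[self.roi_table["roi_id"].to_numpy()] = self.roi_table[column].to_numpy()
        out = np.full(self.roi_mri.shape, np.nan)
        inside = self.roi_mri > 0
        out[inside] = lut[self.roi_mri[inside]]
        return out

    @property
    def tissue_mask_mri(self):
        return self.label_mri > 0

    @property
    def tissue_mask_histo(self):
        return self.label_histo > 0


def _rasterize(regions, grid: RegularGrid):
    label = np.zeros(grid.shape, dtype=np.int16)
    region_id = np.zeros(grid.shape, dtype=np.int16)
    d0, d1 = grid.spacing_mm
    for idx, r in enumerate(regions):
        x0, y0, x1, y1 = r.geometry.bounds
        i0 = max(int(np.floor(x0 / d0)) - 1, 0)
        i1 = min(int(np.ceil(x1 / d0)) + 1, grid.shape[0])
        j0 = max(int(np.floor(y0 / d1)) - 1, 0)
        j1 = min(int(np.ceil(y1 / d1)) + 1, grid.shape[1])
        if i1 <= i0 or j1 <= j0:
            continue
        cx = (np.arange(i0, i1) + 0.5) * d0
        cy = (np.arange(j0, j1) + 0.5) * d1
        gx, gy = np.meshgrid(cx, cy, indexing="ij")
        geom = r.geometry
        shapely.prepare(geom)
        inside = shapely.contains_xy(geom, gx.ravel(), gy.ravel()).reshape(gx.shape)
        sub_label = label[i0:i1, j0:j1]
        sub_id = region_id[i0:i1, j0:j1]
        sub_label[inside] = TISSUE_LABELS[r.label]
        sub_id[inside] = idx + 1
    return label, region_id


def make_phantom(spec: PhantomSpec) -> GroundTruthMaps:
    """Rasterize the spec onto the MRI and histology grids, subdivide each
    region into ROIs along the cord axis, and jitter per-ROI ground truth.

    Raises if two regions with different tissue labels overlap (naming the
    offending regions).
    """
    for i, a in enumerate(spec.regions):
        for b in spec.regions[i + 1:]:
            if a.label != b.label:
                inter = a.geometry.intersection(b.geometry)
                if inter.area > 1e-9:
                    raise ValueError(
                        f"regions {a.label!r} and {b.label!r} overlap "
                        f"(area {inter.area:.3g} mm^2) with conflicting labels"
                    )

    mri_grid, histo_grid = spec.mri_grid, spec.histo_grid
    label_mri, reg_mri = _rasterize(spec.regions, mri_grid)
    label_histo, reg_histo = _rasterize(spec.regions, histo_grid)

    rng = np.random.default_rng(spec.seed)
    roi_mri = np.zeros_like(reg_mri)
    roi_histo = np.zeros_like(reg_histo)
    rows = []
    roi_id = 0
    _, y_mri = mri_grid.pixel_centers()
    _, y_histo = histo_grid.pixel_centers()
    for idx, r in enumerate(spec.regions):
        vox = reg_mri == idx + 1
        if not vox.any():
            warnings.warn(f"region {r.label!r} rasterizes to zero voxels")
            continue
        yv = y_mri[vox]
        edges = np.quantile(yv, np.linspace(0, 1, r.n_rois + 1))
        edges[0], edges[-1] = -np.inf, np.inf
        for b in range(r.n_rois):
            roi_id += 1
            band_mri = vox & (y_mri >= edges[b]) & (y_mri < edges[b + 1])
            band_histo = (reg_histo == idx + 1) & (y_histo >= edges[b]) & (
                y_histo < edges[b + 1]
            )
            roi_mri[band_mri] = roi_id
            roi_histo[band_histo] = roi_id
            j = r.jitter_rel

            def jit(v, lo=0.0, hi=1.0):
                if j == 0:
                    return float(v)
                return float(np.clip(v * (1.0 + j * rng.standard_normal()), lo, hi))

            row = dict(
                roi_id=roi_id,
                region_label=r.label,
                tissue=TISSUE_LABELS[r.label],
                odi=jit(r.odi_true, 1e-4, 0.9999),
                ndi=jit(r.ndi_true),
                ivf=jit(r.ivf_true),
                dot=jit(r.dot_true),
                mu_angle_deg=float(
                    np.mod(r.mu_angle_deg + r.jitter_mu_deg * rng.standard_normal(), 180.0)
                ),
                n_voxels=int(band_mri.sum()),
            )
            for s in STAINS:
                v = r.stain_fraction_true[s]
                row[s] = v if v in (0.0, 1.0) else jit(v, 0.0, 1.0)
            rows.append(row)
    table = pd.DataFrame(rows)
    return GroundTruthMaps(
        spec, mri_grid, histo_grid, label_mri, roi_mri, label_histo, roi_histo, table
    )


def simulate_dwi(gt: GroundTruthMaps, protocol: AcquisitionProtocol,
                 snr_b0: float | None = None, seed: int = 0, s0: float = 1.0):
    """Noisy multi-shell diffusion volume from the phantom ground truth.

    The noise-free signal is the Watson-stick forward model evaluated with
    each ROI's true parameters; Rician noise is the magnitude of a complex
    Gaussian perturbation with ``sigma = s0 / snr_b0`` per channel.
    ``snr_b0 = inf`` returns the noise-free signal exactly.
    """
    snr = gt.spec.snr_b0 if snr_b0 is None else snr_b0
    if not snr > 0:
        raise ValueError("snr_b0 must be positive (may be inf)")
    required = ["odi", "ndi", "ivf", "dot", "mu_angle_deg"]
    for col in required:
        if col not in gt.roi_table.columns:
            raise ValueError(f"ground truth lacks required map {col!r}")

    n = len(protocol)
    nx, ny = gt.mri_grid.shape
    signal = np.zeros((nx, ny, 1, n))
    for _, row in gt.roi_table.iterrows():
        ang = np.deg2rad(row["mu_angle_deg"])
        p = NoddiParams(
            s0=s0,
            v_iso=row["ivf"],
            v_ir=row["dot"],
            v_in=row["ndi"],
            kappa=kappa_from_odi(row["odi"]),
            mu=(np.cos(ang), np.sin(ang), 0.0),
        )
        s = noddi_signal(p, protocol)
        signal[gt.roi_mri == row["roi_id"], 0, :] = s
    inside = gt.roi_mri > 0
    if np.isfinite(snr):
        rng = np.random.default_rng(seed)
        sigma = s0 / snr
        re = signal + sigma * rng.standard_normal(signal.shape)
        im = sigma * rng.standard_normal(signal.shape)
        signal = np.hypot(re, im)
        signal[~inside] = 0.0
    vx, vy = gt.spec.voxel_size_mm
    return DwiVolume(signal, inside[:, :, None], (vx, vy, 0.8))


def _stroke_endpoints(centers, angles, lengths):
    dx = 0.5 * lengths * np.cos(angles)
    dy = 0.5 * lengths * np.sin(angles)
    p0 = centers + np.stack([-dx, -dy], axis=1)
    p1 = centers + np.stack([dx, dy], axis=1)
    return p0, p1


def simulate_fiber_image(gt: GroundTruthMaps, spec: PhantomSpec | None = None,
                         seed: int = 0, return_strokes: bool = False):
    """Silver-staining-like image: dark strokes on a bright background.

    Per ROI, stroke axial orientations are drawn from the circular Watson
    distribution with the concentration implied by the ROI's true ODI via
    ``kappa_from_odi`` (the same kappa as the 3-D model — the mapping is a
    monotone correspondence, not an identity), and stroke count scales with
    the ROI's true NDI.  Zero NDI yields a background-only region.

    Returns the image, plus a stroke table (center, angle, roi) when
    ``return_strokes`` is set.
    """
    from skimage.draw import line_aa

    spec = spec or gt.spec
    if gt.label_histo is None:
        raise ValueError("histology-grid label map is required")
    rng = np.random.default_rng(seed)
    shape = gt.histo_grid.shape
    img = np.full(shape, 0.95, dtype=np.float32)
    img[gt.tissue_mask_histo] = 0.85

    flat_roi = gt.roi_histo.ravel()
    order = np.argsort(flat_roi, kind="stable")
    sorted_roi = flat_roi[order]
    stroke_rows = []
    mean_len_px = 100.0 / spec.histo_pixel_um
    for _, row in gt.roi_table.iterrows():
        rid = int(row["roi_id"])
        lo, hi = np.searchsorted(sorted_roi, [rid, rid + 1])
        if hi == lo:
            continue
        area_px = hi - lo
        n_strokes = int(round(
            _STROKE_COVERAGE_PER_NDI * row["ndi"] * area_px / mean_len_px
        ))
        if n_strokes == 0:
            continue
        pix = order[rng.integers(lo, hi, size=n_strokes)]
        ci = pix // shape[1] + rng.uniform(-0.5, 0.5, n_strokes)
        cj = pix % shape[1] + rng.uniform(-0.5, 0.5, n_strokes)
        kappa = kappa_from_odi(row["odi"])
        angles = sample_axial_angles(np.deg2rad(row["mu_angle_deg"]), kappa,
                                     n_strokes, rng)
        lengths = rng.uniform(0.6, 1.4, n_strokes) * mean_len_px
        p0, p1 = _stroke_endpoints(np.stack([ci, cj], axis=1), angles, lengths)
        for m in range(n_strokes):
            rr, cc, val = line_aa(
                int(round(p0[m, 0])), int(round(p0[m, 1])),
                int(round(p1[m, 0])), int(round(p1[m, 1])),
            )
            keep = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1]) & (
                val >= 0.25
            )
            rr, cc = rr[keep], cc[keep]
            # silver impregnation is near-binary: stroke pixels go uniformly
            # dark (the anti-aliased trace only selects which pixels belong)
            img[rr, cc] = 0.10
        if return_strokes:
            stroke_rows.append(pd.DataFrame({
                "roi_id": rid, "angle_rad": angles, "i": ci, "j": cj,
                "length_px": lengths,
            }))
    out = HistologyImage(img, spec.histo_pixel_um, tissue_mask=gt.tissue_mask_histo)
    if return_strokes:
        strokes = (pd.concat(stroke_rows, ignore_index=True) if stroke_rows
                   else pd.DataFrame(columns=["roi_id", "angle_rad", "i", "j",
                                              "length_px"]))
        return out, strokes
    return out


def simulate_stain_image(gt: GroundTruthMaps, stain: str, seed: int = 0):
    """Immunostain-like image: dark blobs whose expected covered fraction
    per ROI equals the ROI's true staining fraction.

    Blobs are disks of a seeded Boolean (Poisson-intensity) process: with
    disk area ``a`` and target fraction ``f``, centers are placed at rate
    ``lambda = -ln(1 - f)/a`` over the ROI dilated by the disk radius and
    clipped to the ROI, so coverage is unbiased up to the region boundary.
    ``f = 0`` gives zero stained pixels; ``f = 1`` fills the ROI.
    """
    if stain not in STAINS:
        raise ValueError(f"unknown stain {stain!r}; expected one of {STAINS}")
    from scipy.ndimage import binary_dilation

    rng = np.random.default_rng(seed)
    shape = gt.histo_grid.shape
    img = np.full(shape, 0.95, dtype=np.float32)
    img[gt.tissue_mask_histo] = 0.80

    r = _BLOB_RADIUS_PX
    di, dj = np.mgrid[-r:r + 1, -r:r + 1]
    disk = np.flatnonzero((di**2 + dj**2 <= r**2).ravel())
    offs_i, offs_j = di.ravel()[disk], dj.ravel()[disk]
    disk_area = float(len(disk))
    structure = (di**2 + dj**2) <= r**2

    from scipy.ndimage import find_objects

    stained_total = np.zeros(shape, dtype=bool)
    slices = find_objects(gt.roi_histo)
    for _, row in gt.roi_table.iterrows():
        f = float(row[stain])
        rid = int(row["roi_id"])
        sl = slices[rid - 1] if rid - 1 < len(slices) else None
        if sl is None or f <= 0:
            continue
        # pad the bounding box by the disk radius so boundary blobs survive
        i0 = max(sl[0].start - r, 0)
        i1 = min(sl[0].stop + r, shape[0])
        j0 = max(sl[1].start - r, 0)
        j1 = min(sl[1].stop + r, shape[1])
        roi = gt.roi_histo[i0:i1, j0:j1] == rid
        sub_shape = roi.shape
        if f >= 1.0 - 1e-9:
            stained_total[i0:i1, j0:j1] |= roi
            continue
        support = binary_dilation(roi, structure=structure)
        sup_idx = np.flatnonzero(support.ravel())
        lam = -np.log1p(-f) / disk_area
        n_blobs = int(round(lam * sup_idx.size))
        if n_blobs == 0:
            continue
        centers = sup_idx[rng.integers(0, sup_idx.size, size=n_blobs)]
        ci, cj = centers // sub_shape[1], centers % sub_shape[1]
        canvas = np.zeros(sub_shape, dtype=bool)
        for oi, oj in zip(offs_i, offs_j):
            ii = ci + oi
            jj = cj + oj
            ok = (ii >= 0) & (ii < sub_shape[0]) & (jj >= 0) & (jj < sub_shape[1])
            canvas[ii[ok], jj[ok]] = True
        stained_total[i0:i1, j0:j1] |= canvas & roi
    img[stained_total] = 0.10
    return HistologyImage(img, gt.spec.histo_pixel_um,
                          tissue_mask=gt.tissue_mask_histo)
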