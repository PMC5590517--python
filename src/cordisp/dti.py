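"""Diffusion tensor fitting by weighted linear least squares.

The tensor model ``ln S = ln s0 - b g^T D g`` is fitted only to
measurements in the Gaussian diffusion regime (``b <= b_max``, default
4680 s/mm^2).  Weights are the squared observed signals, the standard
first-order variance correction for the log transform.  Eigenvalues are
reported as fitted — negative eigenvalues raise a QC flag rather than being
clamped; FA is computed on the raw eigenvalues and clipped to [0, 1] only
in the map output.
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import DwiVolume, ParameterMaps
from .protocol import AcquisitionProtocol

__all__ = ["fit_dti", "fa_from_eigenvalues", "tensor_design_matrix"]

log = logging.getLogger(__name__)


def fa_from_eigenvalues(evals):
    """Fractional anisotropy from tensor eigenvalues (last axis length 3)."""
    evals = np.asarray(evals, dtype=float)
    mean = evals.mean(axis=-1, keepdims=True)
    num = np.sum((evals - mean) ** 2, axis=-1)
    den = np.sum(evals**2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * num / den)
    return fa


def tensor_design_matrix(bvals, bvecs):
    """Design matrix for ``[ln s0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz]``.

    b-values are converted to ms/um^2 so tensors come out in um^2/ms.
    """
    b = np.asarray(bvals, dtype=float) * 1e-3
    g = np.asarray(bvecs, dtype=float)
    return np.column_stack(
        [
            np.ones_like(b),
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2 * b * g[:, 0] * g[:, 1],
            -2 * b * g[:, 0] * g[:, 2],
            -2 * b * g[:, 1] * g[:, 2],
        ]
    )


def _tensor_from_coeffs(d):
    dxx, dyy, dzz, dxy, dxz, dyz = d
    return np.array([[dxx, dxy, dxz], [dxy, dyy, dyz], [dxz, dyz, dzz]])


def fit_dti(dwi: DwiVolume, protocol: AcquisitionProtocol, b_max=4680.0):
    """Fit the tensor voxel-wise; returns FA/AD/RD/MD, the tensor, the
    principal eigenvector ``v1`` and QC flags.

    Raises if fewer than 7 measurements (including a b=0) survive the
    ``b <= b_max`` filter.  Voxels with non-positive signals have those
    measurements excluded; a voxel left with fewer than 7 usable
    measurements is reported as NaN with ``converged`` 0.
    """
    if len(protocol) != dwi.n_measurements:
        raise ValueError("protocol length does not match the signal")
    keep = protocol.bvals <= b_max
    if keep.sum() < 7 or not np.any(protocol.bvals[keep] == 0):
        raise ValueError(
            f"need >= 7 measurements with b <= {b_max} including a b=0"
        )
    X = tensor_design_matrix(protocol.bvals[keep], protocol.bvecs[keep])

    shape = dwi.signal.shape[:3]
    nan = np.full(shape, np.nan)
    maps = {
        "FA": nan.copy(),
        "AD": nan.copy(),
        "RD": nan.copy(),
        "MD": nan.copy(),
        "s0": nan.copy(),
        "tensor": np.full(shape + (3, 3), np.nan),
        "v1": np.full(shape + (3,), np.nan),
        "negative_eig": np.zeros(shape, dtype=bool),
        "converged": np.zeros(shape, dtype=int),
    }

    n_excluded = 0
    for i, j, k in np.argwhere(dwi.mask):
        s = dwi.signal[i, j, k, keep]
        pos = s > 0
        if not pos.all():
            n_excluded += 1
        if pos.sum() < 7:
            continue
        Xv = X[pos]
        y = np.log(s[pos])
        w = s[pos] ** 2
        XtW = Xv.T * w
        try:
            beta = np.linalg.solve(XtW @ Xv, XtW @ y)
        except np.linalg.LinAlgError:
            continue
        D = _tensor_from_coeffs(beta[1:])
        evals, evecs = np.linalg.eigh(D)  # ascending
        maps["tensor"][i, j, k] = D
        maps["s0"][i, j, k] = np.exp(beta[0])
        maps["AD"][i, j, k] = evals[2]
        maps["RD"][i, j, k] = 0.5 * (evals[0] + evals[1])
        maps["MD"][i, j, k] = evals.mean()
        maps["FA"][i, j, k] = np.clip(fa_from_eigenvalues(evals), 0.0, 1.0)
        maps["v1"][i, j, k] = evecs[:, 2]
        maps["negative_eig"][i, j, k] = bool(evals[0] < 0)
        maps["converged"][i, j, k] = 1

    if n_excluded:
        log.warning(
            "fit_dti: excluded non-positive signals in %d voxel(s)", n_excluded
        )
    return ParameterMaps(maps, "DTI", shape, {"b_max": b_max})
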