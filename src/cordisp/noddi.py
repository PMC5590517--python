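"""Watson-dispersed stick-and-tortuosity diffusion model (ex-vivo variant).

The model decomposes the diffusion-weighted signal of a voxel into

* free water (isotropic Gaussian diffusion with diffusivity ``d_iso``),
* an isotropically *restricted* ("dot") pool with no attenuation at any b,
  as commonly observed in fixed ex-vivo tissue,
* intra-neurite water: zero-radius cylinders (sticks, axial diffusivity
  ``d_par``) whose orientations follow a Watson distribution, and
* extra-neurite water: an anisotropic Gaussian tensor with tortuosity
  ``d_perp = d_par * (1 - v_in)``, orientation-averaged under the same
  Watson distribution.

With ``v_iso`` the free-water fraction, ``v_ir`` the restricted fraction of
the non-free tissue signal and ``v_in`` the stick fraction of the mobile
tissue water:

    S(b, g) = s0 * [ v_iso * exp(-b d_iso)
                     + (1 - v_iso) * ( v_ir
                                       + (1 - v_ir) * ( v_in * A_in
                                                        + (1 - v_in) * A_en ) ) ]

``A_in`` is the Watson-averaged stick signal, computed here exactly (to
quadrature accuracy) by reducing the spherical integral to one dimension:
the integrand ``exp(n^T B n)`` with ``B = kappa mu mu^T - b d_par g g^T``
has an azimuthal integral in closed form (a Bessel ``I0``), leaving a smooth
1-D integral handled by fixed-order Gauss-Legendre quadrature.  The same
rule evaluates the Watson normalizer, so ``S(b=0) = s0`` holds exactly.

Voxel-wise fitting uses a coarse dictionary search (direction initialized
from a diffusion-tensor fit) followed by Levenberg-Marquardt refinement in
transformed coordinates (logistic for fractions, log for ``kappa``).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

from .containers import DwiVolume, ParameterMaps
from .protocol import AcquisitionProtocol
from .watson import kappa_from_odi, odi_from_kappa, watson_tau1

__all__ = [
    "NoddiParams",
    "NoddiFitConfig",
    "watson_stick_average",
    "noddi_signal",
    "fit_noddi",
]

#: fixed intrinsic (stick) diffusivity, um^2/ms
D_PAR_DEFAULT = 1.50
#: free-water diffusivity of the phosphate buffer at 35 C, um^2/ms
D_ISO_DEFAULT = 2.0


@functools.lru_cache(maxsize=8)
def _gauss_legendre(n):
    u, w = np.polynomial.legendre.leggauss(n)
    return u, w


def _axial_exp_integral(lam1, lam2, lam3, n_nodes):
    """``(1/2pi) * Int_{S^2} exp(sum_i lam_i n_i^2) dOmega`` for sorted
    eigenvalues ``lam1 >= lam2 >= lam3`` (arrays broadcast together).

    Polar axis taken along the smallest eigenvalue so the integrand peaks
    smoothly at the equator; the azimuthal integral is ``2 pi exp(s m)
    I0(s d)`` with ``s = 1 - u^2``.
    """
    u, w = _gauss_legendre(n_nodes)
    a1 = lam1 - lam3
    d = 0.5 * (a1 - (lam2 - lam3))
    s = 1.0 - u**2  # (n_nodes,)
    shape = np.broadcast_shapes(np.shape(a1), np.shape(d), np.shape(lam3))
    a1 = np.broadcast_to(a1, shape)[..., None]
    d = np.broadcast_to(d, shape)[..., None]
    lam3 = np.broadcast_to(lam3, shape)[..., None]
    integrand = np.exp(lam3 + s * a1) * special.i0e(s * d)
    return integrand @ w


def watson_stick_average(kappa, bd, cos_angle, n_nodes=128):
    """Watson-averaged stick signal ``E[exp(-bd (g.n)^2)]``, ``n ~ Watson``.

    Parameters
    ----------
    kappa : float or array
        Watson concentration (``inf`` accepted: perfectly parallel sticks).
    bd : array
        Product of b-value and stick diffusivity (dimensionless; b in
        ms/um^2 times d in um^2/ms).
    cos_angle : array
        Cosine of the angle between gradient ``g`` and mean axis ``mu``.
    n_nodes : int
        Order of the Gauss-Legendre rule.  The default resolves
        concentrations up to kappa ~ 130 and ``bd`` up to ~30 to well below
        1e-4 relative error.
    """
    kappa = np.asarray(kappa, dtype=float)
    bd = np.asarray(bd, dtype=float)
    c = np.asarray(cos_angle, dtype=float)
    if np.all(np.isinf(kappa)):
        return np.exp(-bd * c**2)
    if np.any(np.isinf(kappa)):
        raise ValueError("kappa must be all finite or all infinite")
    if np.any(kappa < 0):
        raise ValueError("kappa must be non-negative")
    s2 = np.clip(1.0 - c**2, 0.0, 1.0)
    tr = kappa - bd
    disc = np.sqrt(tr**2 + 4.0 * kappa * bd * s2)
    lp = 0.5 * (tr + disc)
    lm = 0.5 * (tr - disc)
    lam1 = np.maximum(lp, 0.0)
    lam3 = np.minimum(lm, 0.0)
    lam2 = tr - lp - lm  # the zero eigenvalue, written to survive broadcasting
    # sort the middle value explicitly
    lam2 = np.clip(lam2, lam3, lam1)
    num = _axial_exp_integral(lam1, lam2, lam3, n_nodes)
    den = _axial_exp_integral(kappa, np.zeros_like(kappa), np.zeros_like(kappa), n_nodes)
    return num / den


@dataclass(frozen=True)
class NoddiParams:
    """Single-voxel model parameters.

    Fractions: ``v_iso`` (free water), ``v_ir`` (restricted fraction of the
    non-free tissue signal), ``v_in`` (stick fraction of mobile tissue
    water).  ``kappa`` is the Watson concentration (``inf`` allowed);
    ``mu`` the unit mean neurite axis.
    """

    s0: float = 1.0
    v_iso: float = 0.05
    v_ir: float = 0.1
    v_in: float = 0.6
    kappa: float = 6.0
    mu: tuple = (1.0, 0.0, 0.0)
    d_par: float = D_PAR_DEFAULT
    d_iso: float = D_ISO_DEFAULT

    def __post_init__(self):
        if self.s0 <= 0:
            raise ValueError("s0 must be positive")
        for name in ("v_iso", "v_ir", "v_in"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not self.kappa > 0:
            raise ValueError("kappa must be positive")
        if self.d_par <= 0 or self.d_iso <= 0:
            raise ValueError("diffusivities must be positive")
        mu = np.asarray(self.mu, dtype=float)
        if mu.shape != (3,) or not np.isclose(np.linalg.norm(mu), 1.0, atol=1e-8):
            raise ValueError("mu must be a unit 3-vector")
        object.__setattr__(self, "mu", tuple(mu))

    @property
    def odi(self):
        return odi_from_kappa(self.kappa)


def noddi_signal(params: NoddiParams, protocol: AcquisitionProtocol, n_nodes=128):
    """Noise-free model signal for every measurement of ``protocol``."""
    b = protocol.bvals * 1e-3  # s/mm^2 -> ms/um^2
    g = protocol.bvecs
    mu = np.asarray(params.mu)
    c = g @ mu
    a_in = watson_stick_average(params.kappa, b * params.d_par, c, n_nodes=n_nodes)
    d_perp = params.d_par * (1.0 - params.v_in)
    tau1 = watson_tau1(params.kappa)
    d_ax = d_perp + (params.d_par - d_perp) * tau1
    d_rad = d_perp + (params.d_par - d_perp) * (1.0 - tau1) / 2.0
    a_en = np.exp(-b * (d_ax * c**2 + d_rad * (1.0 - c**2)))
    a_iso = np.exp(-b * params.d_iso)
    tissue = params.v_ir + (1.0 - params.v_ir) * (
        params.v_in * a_in + (1.0 - params.v_in) * a_en
    )
    return params.s0 * (params.v_iso * a_iso + (1.0 - params.v_iso) * tissue)


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------


@dataclass
class NoddiFitConfig:
    """Controls for the voxel-wise fit; all defaults deterministic."""

    d_par: float = D_PAR_DEFAULT
    d_iso: float = D_ISO_DEFAULT
    fit_dot: bool = True  # fit v_ir per voxel (False pins it at dot_value)
    dot_value: float = 0.0
    refine: bool = True
    refine_mu: bool = True  # False keeps the DTI-derived direction
    objective: str = "gaussian"  # or "rician"
    rician_sigma: float | None = None  # required for the Rician objective
    max_nfev: int | None = None
    xtol: float = 1e-12
    ftol: float = 1e-12
    n_nodes: int = 128
    dti_b_max: float = 4680.0
    grid_v_iso: tuple = (0.01, 0.05, 0.12, 0.25, 0.45, 0.7, 0.95)
    grid_v_ir: tuple = (0.02, 0.08, 0.18, 0.35)
    grid_v_in: tuple = (0.05, 0.18, 0.32, 0.45, 0.58, 0.7, 0.82, 0.95)
    grid_odi: tuple = (0.03, 0.05, 0.09, 0.15, 0.24, 0.36, 0.5, 0.67, 0.85)
    chunk_size: int = 256

    def __post_init__(self):
        if self.d_par <= 0 or self.d_iso <= 0:
            raise ValueError("diffusivities must be positive")
        if self.objective not in ("gaussian", "rician"):
            raise ValueError("objective must be 'gaussian' or 'rician'")
        if self.objective == "rician" and not self.rician_sigma:
            raise ValueError("the Rician objective requires rician_sigma")


def _logit(p):
    p = np.clip(p, 1e-9, 1 - 1e-9)
    return np.log(p / (1 - p))


def _expit(x):
    return special.expit(x)


def _fix_hemisphere(mu):
    """Sign convention for the axial direction: z >= 0, ties -> y >= 0,
    then x >= 0."""
    mu = np.asarray(mu, dtype=float)
    for k in (2, 1, 0):
        if abs(mu[k]) > 1e-12:
            return mu if mu[k] > 0 else -mu
    return mu


def _grid_search(y, c, bd_par, b_ms, cfg):
    """Vectorized dictionary search over (v_iso, v_ir, v_in, odi).

    Parameters
    ----------
    y : (n_vox, n_dw) normalized DW signals
    c : (n_vox, n_dw) cosines g.mu per voxel (mu from the tensor fit)
    bd_par, b_ms : (n_dw,) b*d_par and b in ms/um^2

    Returns per-voxel best (v_iso, v_ir, v_in, kappa) and SSE.
    """
    n_vox = y.shape[0]
    a_iso = np.exp(-b_ms * cfg.d_iso)  # (n_dw,)
    kappas = kappa_from_odi(np.asarray(cfg.grid_odi))
    a_in = {}
    for k in kappas:
        a_in[k] = watson_stick_average(k, bd_par, c, n_nodes=min(cfg.n_nodes, 96))
    best_sse = np.full(n_vox, np.inf)
    best = np.zeros((n_vox, 4))
    for ik, k in enumerate(kappas):
        tau1 = watson_tau1(k)
        for v_in in cfg.grid_v_in:
            d_perp = cfg.d_par * (1.0 - v_in)
            d_ax = d_perp + (cfg.d_par - d_perp) * tau1
            d_rad = d_perp + (cfg.d_par - d_perp) * (1.0 - tau1) / 2.0
            a_en = np.exp(-b_ms * (d_ax * c**2 + d_rad * (1.0 - c**2)))
            mobile = v_in * a_in[k] + (1.0 - v_in) * a_en  # (n_vox, n_dw)
            for v_ir in cfg.grid_v_ir if cfg.fit_dot else (cfg.dot_value,):
                tissue = v_ir + (1.0 - v_ir) * mobile
                for v_iso in cfg.grid_v_iso:
                    model = v_iso * a_iso + (1.0 - v_iso) * tissue
                    sse = np.sum((model - y) ** 2, axis=1)
                    better = sse < best_sse
                    if np.any(better):
                        best_sse[better] = sse[better]
                        best[better] = (v_iso, v_ir, v_in, k)
    return best, best_sse


# log-kappa clamp: kappa ~ 665 is already parallel to < 0.001 ODI, and
# exp(kappa) must stay below float64 overflow in the quadrature
_LOG_KAPPA_MAX = 6.5


def _voxel_model(x, c_or_angles, bd_par, b_ms, a_iso, cfg, mu_fixed_c):
    v_iso, v_ir, v_in = _expit(x[0]), _expit(x[1]), _expit(x[2])
    kappa = np.exp(np.clip(x[3], -20.0, _LOG_KAPPA_MAX))
    if mu_fixed_c is not None:
        c = mu_fixed_c
    else:
        theta, phi = x[4], x[5]
        mu = np.array(
            [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
        )
        c = c_or_angles @ mu
    if not cfg.fit_dot:
        v_ir = cfg.dot_value
    a_in = watson_stick_average(kappa, bd_par, c, n_nodes=cfg.n_nodes)
    d_perp = cfg.d_par * (1.0 - v_in)
    tau1 = watson_tau1(kappa)
    d_ax = d_perp + (cfg.d_par - d_perp) * tau1
    d_rad = d_perp + (cfg.d_par - d_perp) * (1.0 - tau1) / 2.0
    a_en = np.exp(-b_ms * (d_ax * c**2 + d_rad * (1.0 - c**2)))
    tissue = v_ir + (1.0 - v_ir) * (v_in * a_in + (1.0 - v_in) * a_en)
    return v_iso * a_iso + (1.0 - v_iso) * tissue


def _rician_nll(model, y, sigma):
    # negative log-likelihood of Rician measurements, up to constants
    z = model * y / sigma**2
    return float(
        np.sum(
            0.5 * (model**2) / sigma**2
            - np.log(special.i0e(z))
            - z
        )
    )


def fit_noddi(dwi: DwiVolume, protocol: AcquisitionProtocol, config=None):
    """Voxel-wise model fit; returns maps of IVF, NDI, ODI, dot fraction,
    orientation, s0, objective value and a convergence flag.

    Voxels with non-positive mean b=0 signal are flagged (-1) and excluded
    rather than aborting the fit.
    """
    from .dti import fit_dti  # local import to avoid a cycle

    cfg = config or NoddiFitConfig()
    if len(protocol) != dwi.n_measurements:
        raise ValueError("protocol length does not match the signal")
    if not np.any(protocol.b0_mask):
        raise ValueError("fitting requires at least one b=0 measurement")

    shape = dwi.signal.shape[:3]
    nan = np.full(shape, np.nan)
    maps = {
        "IVF": nan.copy(),
        "NDI": nan.copy(),
        "ODI": nan.copy(),
        "v_ir": nan.copy(),
        "s0": nan.copy(),
        "objective": nan.copy(),
        "converged": np.zeros(shape, dtype=int),
        "mu": np.full(shape + (3,), np.nan),
    }

    vox_idx = np.argwhere(dwi.mask)
    if vox_idx.size == 0:
        return ParameterMaps(maps, "NODDI", shape, {"config": cfg})

    sig = dwi.signal[dwi.mask]  # (n_vox, n_meas)
    s0 = sig[:, protocol.b0_mask].mean(axis=1)
    good = s0 > 0
    bad_idx = vox_idx[~good]
    for i, j, k in bad_idx:
        maps["converged"][i, j, k] = -1

    dw = protocol.dw_mask
    b_ms = protocol.bvals[dw] * 1e-3
    bd_par = b_ms * cfg.d_par
    gdirs = protocol.bvecs[dw]
    a_iso = np.exp(-b_ms * cfg.d_iso)

    # direction initialization from the diffusion tensor
    dti = fit_dti(dwi, protocol, b_max=cfg.dti_b_max)
    v1 = dti["v1"][dwi.mask]  # (n_vox, 3)
    v1 = np.where(np.isfinite(v1).all(axis=1, keepdims=True), v1, [1.0, 0.0, 0.0])

    y_all = sig[good][:, dw] / s0[good, None]
    v1_good = v1[good]
    idx_good = vox_idx[good]
    n_good = y_all.shape[0]

    init = np.zeros((n_good, 4))
    for lo in range(0, n_good, cfg.chunk_size):
        hi = min(lo + cfg.chunk_size, n_good)
        c = v1_good[lo:hi] @ gdirs.T  # (chunk, n_dw)
        init[lo:hi], _ = _grid_search(y_all[lo:hi], c, bd_par, b_ms, cfg)

    for ii in range(n_good):
        y = y_all[ii]
        mu0 = _fix_hemisphere(v1_good[ii])
        v_iso0, v_ir0, v_in0, kappa0 = init[ii]
        theta0 = np.arccos(np.clip(mu0[2], -1, 1))
        phi0 = np.arctan2(mu0[1], mu0[0])
        x0 = np.array([_logit(v_iso0), _logit(v_ir0), _logit(v_in0), np.log(kappa0)])
        mu_fixed_c = None
        if cfg.refine_mu:
            x0 = np.concatenate([x0, [theta0, phi0]])
        else:
            mu_fixed_c = gdirs @ mu0
        if cfg.refine:
            def residuals(x):
                return (
                    _voxel_model(x, gdirs, bd_par, b_ms, a_iso, cfg, mu_fixed_c) - y
                )

            if cfg.objective == "gaussian":
                sol = optimize.least_squares(
                    residuals,
                    x0,
                    method="lm",
                    xtol=cfg.xtol,
                    ftol=cfg.ftol,
                    max_nfev=cfg.max_nfev,
                )
                x, sse, ok = sol.x, 2.0 * sol.cost, sol.status > 0
            else:
                def nll(x):
                    m = _voxel_model(x, gdirs, bd_par, b_ms, a_iso, cfg, mu_fixed_c)
                    return _rician_nll(m, y, cfg.rician_sigma)

                sol = optimize.minimize(nll, x0, method="Nelder-Mead")
                x = sol.x
                sse = float(np.sum(residuals(x) ** 2))
                ok = bool(sol.success)
        else:
            x = x0
            resid = _voxel_model(x0, gdirs, bd_par, b_ms, a_iso, cfg, mu_fixed_c) - y
            sse = float(np.sum(resid**2))
            ok = True

        i, j, k = idx_good[ii]
        maps["IVF"][i, j, k] = _expit(x[0])
        maps["v_ir"][i, j, k] = cfg.dot_value if not cfg.fit_dot else _expit(x[1])
        maps["NDI"][i, j, k] = _expit(x[2])
        maps["ODI"][i, j, k] = odi_from_kappa(
            np.exp(np.clip(x[3], -20.0, _LOG_KAPPA_MAX))
        )
        maps["s0"][i, j, k] = s0[good][ii]
        maps["objective"][i, j, k] = sse
        maps["converged"][i, j, k] = 1 if ok else 0
        if cfg.refine_mu and cfg.refine:
            theta, phi = x[4], x[5]
            mu = np.array(
                [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
            )
        else:
            mu = mu0
        maps["mu"][i, j, k] = _fix_hemisphere(mu / np.linalg.norm(mu))

    return ParameterMaps(maps, "NODDI", shape, {"config": cfg})
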