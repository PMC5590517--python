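"""Slow brute-force reference computations for validation.

These routines deliberately avoid the analytical shortcuts used by the
production code: spherical integrals are evaluated by dense product
quadrature (Gauss-Legendre in the polar cosine times a trapezoidal rule in
azimuth), so they serve as independent oracles for the fast model paths.
They are orders of magnitude slower and intended only for tests and
validation scripts.
"""

from __future__ import annotations

import numpy as np

from .watson import watson_tau1  # noqa: F401  (re-exported for convenience)

__all__ = [
    "sphere_quadrature",
    "bruteforce_watson_stick_average",
    "bruteforce_watson_axis_moment",
    "bruteforce_noddi_signal",
    "circular_variance_of_angles",
]


def sphere_quadrature(n_polar=100, n_azimuth=100):
    """Product quadrature on the unit sphere.

    Returns ``(points, weights)`` with ``n_polar * n_azimuth`` nodes whose
    weights sum to ``4 pi``.
    """
    u, wu = np.polynomial.legendre.leggauss(n_polar)
    phi = (np.arange(n_azimuth) + 0.5) * (2 * np.pi / n_azimuth)
    wphi = 2 * np.pi / n_azimuth
    su = np.sqrt(1 - u**2)
    pts = np.stack(
        [
            np.outer(su, np.cos(phi)).ravel(),
            np.outer(su, np.sin(phi)).ravel(),
            np.outer(u, np.ones_like(phi)).ravel(),
        ],
        axis=1,
    )
    w = np.outer(wu, np.full_like(phi, wphi)).ravel()
    return pts, w


def bruteforce_watson_stick_average(kappa, mu, bd, g, n_polar=100, n_azimuth=100):
    """``E_n~Watson(mu, kappa)[exp(-bd (g.n)^2)]`` by dense quadrature.

    ``bd`` may be an array broadcast against rows of ``g`` (shape (m, 3)).
    """
    pts, w = sphere_quadrature(n_polar, n_azimuth)
    mu = np.asarray(mu, dtype=float)
    wt = w * np.exp(kappa * (pts @ mu) ** 2)
    wt = wt / wt.sum()
    proj2 = (np.atleast_2d(g) @ pts.T) ** 2  # (m, n_nodes)
    return np.exp(-np.atleast_1d(bd)[:, None] * proj2) @ wt


def bruteforce_watson_axis_moment(kappa, mu, n_polar=100, n_azimuth=100):
    """Watson second-moment matrix ``E[n n^T]`` by dense quadrature."""
    pts, w = sphere_quadrature(n_polar, n_azimuth)
    mu = np.asarray(mu, dtype=float)
    wt = w * np.exp(kappa * (pts @ mu) ** 2)
    wt = wt / wt.sum()
    return (pts * wt[:, None]).T @ pts


def bruteforce_noddi_signal(params, protocol, n_polar=100, n_azimuth=100):
    """Model signal with both Watson averages done by dense quadrature.

    The intra-neurite compartment averages the stick *signal*; the
    extra-neurite compartment averages the *tensor* (then exponentiates),
    mirroring the production model's definition.
    """
    b = protocol.bvals * 1e-3
    g = protocol.bvecs
    mu = np.asarray(params.mu)
    a_in = bruteforce_watson_stick_average(
        params.kappa, mu, b * params.d_par, g, n_polar, n_azimuth
    )
    d_perp = params.d_par * (1.0 - params.v_in)
    moment = bruteforce_watson_axis_moment(params.kappa, mu, n_polar, n_azimuth)
    D_en = (params.d_par - d_perp) * moment + d_perp * np.eye(3)
    a_en = np.exp(-b * np.einsum("mi,ij,mj->m", g, D_en, g))
    a_iso = np.exp(-b * params.d_iso)
    tissue = params.v_ir + (1 - params.v_ir) * (
        params.v_in * a_in + (1 - params.v_in) * a_en
    )
    return params.s0 * (params.v_iso * a_iso + (1 - params.v_iso) * tissue)


def circular_variance_of_angles(theta, weights=None):
    """Unweighted (or weighted) axial circular variance of angles in radians.

    ``CV = 1 - |sum w exp(2 i theta)| / sum w`` — direct arithmetic on the
    doubled angles, used as the ground-truth dispersion of generated stroke
    populations.
    """
    theta = np.asarray(theta, dtype=float)
    w = np.ones_like(theta) if weights is None else np.asarray(weights, dtype=float)
    resultant = np.hypot(np.sum(w * np.cos(2 * theta)), np.sum(w * np.sin(2 * theta)))
    return 1.0 - resultant / np.sum(w)
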