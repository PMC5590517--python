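"""Watson distribution utilities for axially symmetric orientation models.

The Watson distribution is the antipodally symmetric analogue of a Gaussian
on the sphere: ``W(n) = C(kappa) * exp(kappa * (mu . n)**2)`` with mean axis
``mu`` and concentration ``kappa > 0``.  It underpins both the dispersed-stick
diffusion model (3-D, on the sphere) and the circle-valued sampling of fiber
stroke orientations in the synthetic histology generator.

The orientation dispersion index (ODI) is the conventional reparameterization
``ODI = (2/pi) * arctan(1/kappa)``, mapping ``kappa -> inf`` (parallel) to 0
and ``kappa -> 0`` (isotropic) to 1.
"""

from __future__ import annotations

import numpy as np
from scipy import special

__all__ = [
    "odi_from_kappa",
    "kappa_from_odi",
    "watson_normalizer",
    "watson_pdf",
    "watson_tau1",
    "sample_axial_angles",
]


def odi_from_kappa(kappa):
    """Orientation dispersion index in (0, 1] from Watson concentration.

    Strictly decreasing; ``kappa = inf`` is accepted and maps to 0.
    """
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa <= 0):
        raise ValueError("kappa must be strictly positive")
    with np.errstate(divide="ignore"):
        out = (2.0 / np.pi) * np.arctan2(1.0, kappa)
    return out if out.ndim else float(out)


def kappa_from_odi(odi):
    """Inverse of :func:`odi_from_kappa`; ``odi`` in (0, 1]."""
    odi = np.asarray(odi, dtype=float)
    if np.any((odi <= 0) | (odi > 1)):
        raise ValueError("odi must lie in (0, 1]")
    with np.errstate(divide="ignore"):
        out = 1.0 / np.tan(np.pi * odi / 2.0)
    return out if out.ndim else float(out)


def watson_normalizer(kappa):
    """Normalizing constant ``Z = 4*pi*M(1/2, 3/2, kappa)`` so that
    ``exp(kappa*(mu.n)^2)/Z`` integrates to one over the sphere."""
    return 4.0 * np.pi * special.hyp1f1(0.5, 1.5, kappa)


def watson_pdf(n, mu, kappa):
    """Watson density at unit vector(s) ``n`` for mean axis ``mu``.

    Parameters
    ----------
    n : array, shape (..., 3)
        Unit evaluation direction(s).
    mu : array, shape (3,)
        Unit mean axis.
    kappa : float
        Concentration, ``kappa >= 0`` (0 gives the uniform density).
    """
    n = np.asarray(n, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    if not np.allclose(np.linalg.norm(mu), 1.0, atol=1e-8):
        raise ValueError("mu must be a unit vector")
    norms = np.linalg.norm(n, axis=-1)
    if not np.allclose(norms, 1.0, atol=1e-8):
        raise ValueError("n must contain unit vectors")
    t = n @ mu
    return np.exp(kappa * t**2) / watson_normalizer(kappa)


def watson_tau1(kappa):
    """Second moment ``<(mu . n)^2>`` under the Watson distribution.

    Equals ``M(3/2, 5/2, kappa) / (3 M(1/2, 3/2, kappa))``; 1/3 at
    ``kappa = 0`` (isotropic) and -> 1 as ``kappa -> inf`` (parallel).
    ``kappa = inf`` is accepted.
    """
    kappa = np.asarray(kappa, dtype=float)
    out = np.empty_like(kappa)
    inf = np.isinf(kappa)
    out[inf] = 1.0
    k = kappa[~inf]
    out[~inf] = special.hyp1f1(1.5, 2.5, k) / (3.0 * special.hyp1f1(0.5, 1.5, k))
    return out if out.ndim else float(out)


def sample_axial_angles(mu_rad, kappa, size, rng):
    """Sample axial angles in [0, pi) from the circular Watson distribution.

    The circle-valued Watson density ``p(theta) propto exp(kappa*cos^2(theta -
    mu))`` becomes, after angle doubling ``psi = 2*theta``, a von Mises density
    with location ``2*mu`` and concentration ``kappa/2`` — so sampling reduces
    to a single von Mises draw.

    Parameters
    ----------
    mu_rad : float
        Mean axis angle in radians.
    kappa : float
        Concentration (0 = uniform axial angles; inf = all parallel).
    size : int
        Number of samples.
    rng : numpy.random.Generator
    """
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    if np.isinf(kappa):
        return np.full(size, mu_rad % np.pi)
    psi = rng.vonmises(2.0 * mu_rad, kappa / 2.0, size=size)
    return (psi / 2.0) % np.pi
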