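"""Diffusion acquisition protocols (b-values and gradient directions).

The default protocol reproduces the six-shell ex-vivo spinal-cord sampling
scheme used throughout this package: 25 b=0 measurements plus shells at
b = 520, 2080, 4680, 8320, 13000 and 18720 s/mm^2 carrying 6, 15, 24, 33,
42 and 51 isotropically distributed directions respectively (196
measurements in total).  Directions are spread by electrostatic-repulsion
optimization on the sphere with antipodal symmetry, from a fixed seed, so
the protocol is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AcquisitionProtocol",
    "default_protocol",
    "DEFAULT_SHELLS",
    "electrostatic_directions",
]

#: (b-value [s/mm^2], number of directions) of the default six-shell scheme.
DEFAULT_SHELLS = (
    (520.0, 6),
    (2080.0, 15),
    (4680.0, 24),
    (8320.0, 33),
    (13000.0, 42),
    (18720.0, 51),
)

DEFAULT_N_B0 = 25


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Multi-shell diffusion sampling scheme.

    Attributes
    ----------
    bvals : ndarray, shape (N,)
        b-values in s/mm^2 (>= 0).
    bvecs : ndarray, shape (N, 3)
        Unit gradient directions for b > 0; the zero vector for b = 0.
    meta : dict
        Optional timing metadata (delta, Delta, TE, TR in ms); stored only.
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float).reshape(-1, 3)
        if bvals.shape[0] != bvecs.shape[0]:
            raise ValueError("bvals and bvecs lengths differ")
        if np.any(bvals < 0):
            raise ValueError("b-values must be non-negative")
        dw = bvals > 0
        norms = np.linalg.norm(bvecs[dw], axis=1)
        if dw.any() and not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("gradient directions for b > 0 must be unit vectors")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    def __len__(self):
        return self.bvals.shape[0]

    @property
    def b0_mask(self):
        return self.bvals == 0

    @property
    def dw_mask(self):
        return self.bvals > 0

    def shells(self):
        """Return {b-value: direction count} for b > 0."""
        vals, counts = np.unique(self.bvals[self.dw_mask], return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def subset(self, mask):
        return AcquisitionProtocol(self.bvals[mask], self.bvecs[mask], dict(self.meta))

    # -- FSL-dialect text I/O ------------------------------------------------

    def save(self, bvals_path, bvecs_path):
        """Write FSL-style ``bvals`` (one row) and ``bvecs`` (3 x N rows)."""
        with open(bvals_path, "w") as fh:
            fh.write(" ".join(f"{b:.6g}" for b in self.bvals) + "\n")
        with open(bvecs_path, "w") as fh:
            for row in self.bvecs.T:
                fh.write(" ".join(f"{v:.9f}" for v in row) + "\n")

    @classmethod
    def load(cls, bvals_path, bvecs_path, **meta):
        bvals = np.loadtxt(bvals_path).ravel()
        bvecs = np.loadtxt(bvecs_path)
        if bvecs.shape[0] == 3 and bvecs.shape != (3, 3):
            bvecs = bvecs.T
        return cls(bvals, bvecs, meta)


def electrostatic_directions(n, seed=0, n_iter=2000, step=0.05):
    """Spread ``n`` unit vectors by minimizing antipodal Coulomb energy.

    Points interact with both each other and each other's antipodes
    (orientations are axial), via damped gradient descent with
    renormalization at each step.  Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("need at least one direction")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, 3))
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    if n == 1:
        return x
    for _ in range(n_iter):
        force = np.zeros_like(x)
        for sign in (1.0, -1.0):
            diff = x[:, None, :] - sign * x[None, :, :]  # (n, n, 3)
            dist2 = np.sum(diff**2, axis=-1)
            np.fill_diagonal(dist2, np.inf)
            if sign < 0:
                # antipode of self is at distance 2; keep that interaction
                np.fill_diagonal(dist2, 4.0)
                np.fill_diagonal(diff[..., 0], 2.0 * x[:, 0])
                np.fill_diagonal(diff[..., 1], 2.0 * x[:, 1])
                np.fill_diagonal(diff[..., 2], 2.0 * x[:, 2])
            force += np.sum(diff / dist2[..., None] ** 1.5, axis=1)
        x = x + step * force / n
        x /= np.linalg.norm(x, axis=1, keepdims=True)
    return x


import functools


@functools.lru_cache(maxsize=4)
def default_protocol(n_b0=DEFAULT_N_B0, shells=DEFAULT_SHELLS, seed=20170815):
    """Build the default six-shell protocol (196 measurements).

    Directions per shell come from :func:`electrostatic_directions` with a
    shell-specific child seed, so every call returns the identical scheme.
    """
    bvals = [np.zeros(n_b0)]
    bvecs = [np.zeros((n_b0, 3))]
    for i, (b, ndir) in enumerate(shells):
        bvals.append(np.full(ndir, float(b)))
        d = electrostatic_directions(ndir, seed=seed + i)
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        bvecs.append(d)
    return AcquisitionProtocol(
        np.concatenate(bvals),
        np.vstack(bvecs),
        {"delta_ms": 12.0, "Delta_ms": 18.0, "TE_ms": 39.5, "TR_ms": 2200.0},
    )
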