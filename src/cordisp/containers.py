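"""In-memory containers for diffusion volumes and fitted parameter maps."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DwiVolume", "ParameterMaps"]


@dataclass
class DwiVolume:
    """4-D diffusion-weighted signal ``(x, y, z, measurement)`` with mask.

    ``voxel_size_mm`` is (dx, dy, dz).  The signal must be non-negative and
    its 4th dimension must match the acquisition protocol length.
    """

    signal: np.ndarray
    mask: np.ndarray
    voxel_size_mm: tuple = (0.16, 0.20, 0.8)

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4-D (x, y, z, measurement)")
        if np.any(self.signal < 0):
            raise ValueError("signal must be non-negative")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.signal.shape[:3]:
            raise ValueError("mask shape must match the first three signal axes")

    @property
    def n_measurements(self):
        return self.signal.shape[3]


@dataclass
class ParameterMaps:
    """Named per-voxel maps from a model fit (NODDI or DTI).

    ``maps`` values share the spatial shape; vector/tensor-valued entries
    (e.g. ``mu``, ``tensor``) carry trailing component axes.
    """

    maps: dict
    modality: str
    spatial_shape: tuple
    meta: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.maps[key]

    def __contains__(self, key):
        return key in self.maps

    def keys(self):
        return self.maps.keys()
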