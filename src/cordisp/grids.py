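"""Regular 2-D physical grids shared by MRI slices, histology images and
patch maps.

Array axis 0 runs along the first physical coordinate (x) and axis 1 along
the second (y); the physical coordinate of a pixel is its center:
``x = origin_x + (i + 0.5) * dx``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RegularGrid"]


@dataclass(frozen=True)
class RegularGrid:
    shape: tuple  # (n0, n1)
    spacing_mm: tuple  # (d0, d1)
    origin_mm: tuple = (0.0, 0.0)  # outer corner of pixel (0, 0)

    @property
    def extent_mm(self):
        return (self.shape[0] * self.spacing_mm[0], self.shape[1] * self.spacing_mm[1])

    def pixel_centers(self):
        """Center coordinate arrays (axis 0, axis 1), each of ``self.shape``."""
        c0 = self.origin_mm[0] + (np.arange(self.shape[0]) + 0.5) * self.spacing_mm[0]
        c1 = self.origin_mm[1] + (np.arange(self.shape[1]) + 0.5) * self.spacing_mm[1]
        return np.meshgrid(c0, c1, indexing="ij")

    def to_index(self, c0, c1):
        """Fractional array indices of physical points (for interpolation)."""
        i0 = (np.asarray(c0) - self.origin_mm[0]) / self.spacing_mm[0] - 0.5
        i1 = (np.asarray(c1) - self.origin_mm[1]) / self.spacing_mm[1] - 0.5
        return i0, i1
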