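"""Sheet geometry: mapping between abstract sheet coordinates and unit grids.

All sheets live in a common visual coordinate frame.  A sheet of ``density`` d
and half-extent ``radius`` r holds an n x n grid of units (n = 2*r*d) with
spacing 1/d, centered on the origin.  Row index increases with y, column index
with x, so ``activity[j, i]`` is the unit at ``(x_i, y_j)``.  Area-preserving
coordinate mapping between sheets of different density is then simply identity
on coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SheetGeometry"]


@dataclass(frozen=True)
class SheetGeometry:
    name: str
    density: int
    radius: float

    def __post_init__(self):
        if self.density <= 0 or self.radius <= 0:
            raise ValueError(f"sheet {self.name}: density and radius must be positive")
        n = 2 * self.radius * self.density
        if abs(n - round(n)) > 1e-6:
            raise ValueError(
                f"sheet {self.name}: 2*radius*density = {n} is not integral"
            )

    @property
    def n(self) -> int:
        """Units per side."""
        return int(round(2 * self.radius * self.density))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n, self.n)

    @property
    def n_units(self) -> int:
        return self.n * self.n

    def coords_1d(self) -> np.ndarray:
        """Sheet coordinates of unit centers along one axis."""
        n = self.n
        return (np.arange(n) - (n - 1) / 2.0) / self.density

    def grid(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of shape (n, n)."""
        c = self.coords_1d()
        x, y = np.meshgrid(c, c)
        return x, y

    def nearest_index(self, coord: np.ndarray) -> np.ndarray:
        """Nearest grid index along one axis for each coordinate value."""
        n = self.n
        idx = np.rint(coord * self.density + (n - 1) / 2.0).astype(np.int64)
        return idx
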