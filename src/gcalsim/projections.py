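"""Connection fields: per-target-unit weight patches between (or within) sheets.

A projection links every target unit to the source units within a circular
radius of its (retinotopically mapped) position.  Patches have a fixed square
footprint on the source grid; entries outside the circle or outside the source
sheet carry weight 0 and a 0 mask so they never gain weight under Hebbian
learning (truncate-and-renormalize boundary handling).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .config import ConfigurationError
from .geometry import SheetGeometry

__all__ = ["PatchSet", "Projection", "build_patches", "gaussian_weights", "random_envelope_weights"]


@dataclass
class PatchSet:
    """Geometry of the connection patches: indices, mask and center distances.

    Treated as immutable once built; model-state copies share it.  ``dist2``
    is only needed while constructing initial weights and may be freed.
    """

    idx: np.ndarray  # (n_target, P) int32 flat indices into the source sheet
    mask: np.ndarray  # (n_target, P) float64, 1.0 where a connection exists
    dist2: np.ndarray | None  # (n_target, P) squared sheet-coordinate distance


def build_patches(
    src: SheetGeometry,
    tgt: SheetGeometry,
    radius: float,
    name: str,
    require_full_fit: bool = False,
) -> PatchSet:
    """Connection patches from ``src`` onto every unit of ``tgt`` within ``radius``."""
    if require_full_fit:
        # validate before allocating patch arrays: the outermost target unit's
        # circular field must lie within the source sheet
        t_edge = (tgt.n - 1) / (2.0 * tgt.density)
        margin = 0.5 / src.density
        if t_edge + radius > src.radius + margin + 1e-9:
            raise ConfigurationError(
                f"projection {name!r}: connection fields of radius {radius} extend "
                f"beyond the {src.name} sheet bounds (half-extent {src.radius})"
            )
    h = int(math.floor(radius * src.density + 0.5 + 1e-9))
    h = min(h, src.n - 1)
    tx, ty = tgt.grid()
    tx = tx.ravel()
    ty = ty.ravel()
    cx = src.nearest_index(tx)
    cy = src.nearest_index(ty)
    offs = np.arange(-h, h + 1)
    # patch layout: row-major over (dy, dx)
    ix = cx[:, None, None] + offs[None, None, :]
    iy = cy[:, None, None] + offs[None, :, None]
    n_src = src.n
    inside = (ix >= 0) & (ix < n_src) & (iy >= 0) & (iy < n_src)
    sx = (ix - (n_src - 1) / 2.0) / src.density
    sy = (iy - (n_src - 1) / 2.0) / src.density
    d2 = (sx - tx[:, None, None]) ** 2 + (sy - ty[:, None, None]) ** 2
    in_circle = d2 <= radius**2 + 1e-12
    if require_full_fit and np.any(in_circle & ~inside):
        raise ConfigurationError(
            f"projection {name!r}: connection fields of radius {radius} extend "
            f"beyond the {src.name} sheet bounds (half-extent {src.radius})"
        )
    mask = (inside & in_circle).astype(np.float64)
    idx = (np.clip(iy, 0, n_src - 1) * n_src + np.clip(ix, 0, n_src - 1)).astype(np.int32)
    P = (2 * h + 1) ** 2
    return PatchSet(
        idx=idx.reshape(-1, P),
        mask=mask.reshape(-1, P),
        dist2=d2.reshape(-1, P),
    )


def gaussian_weights(patches: PatchSet, sigma: float) -> np.ndarray:
    """Isotropic Gaussian weights over the patch, normalized to unit sum per unit."""
    w = np.exp(-patches.dist2 / (2.0 * sigma**2)) * patches.mask
    return w / w.sum(axis=1, keepdims=True)


def random_envelope_weights(patches: PatchSet, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Uniform random weights under a Gaussian envelope (unnormalized)."""
    u = rng.random(patches.idx.shape)
    return u * np.exp(-patches.dist2 / (2.0 * sigma**2)) * patches.mask


@dataclass
class Projection:
    """A weighted projection with (optionally plastic) per-unit patches.

    ``w`` rows sum to 1 for every target unit (joint across channels for the
    afferent projection, where ``w`` concatenates the On and Off patches).
    """

    name: str
    src_names: tuple
    patches: PatchSet
    w: np.ndarray
    plastic: bool = False

    def activate(self, *src_flats: np.ndarray) -> np.ndarray:
        """Weighted sum of source activity per target unit."""
        if len(src_flats) == 1:
            return _kernels.project(src_flats[0], self.patches.idx, self.w)
        # joint afferent: the same patch indices into each channel, weights
        # concatenated [on | off]
        p = self.patches.idx.shape[1]
        acc = _kernels.project(src_flats[0], self.patches.idx, np.ascontiguousarray(self.w[:, :p]))
        acc += _kernels.project(src_flats[1], self.patches.idx, np.ascontiguousarray(self.w[:, p:]))
        return acc

    def gather_pre(self, *src_flats: np.ndarray) -> np.ndarray:
        """Presynaptic activity arranged like ``w`` (for Hebbian updates)."""
        if len(src_flats) == 1:
            return src_flats[0][self.patches.idx]
        return np.concatenate(
            [src_flats[0][self.patches.idx], src_flats[1][self.patches.idx]], axis=1
        )

    @property
    def full_mask(self) -> np.ndarray:
        """Mask matching the layout of ``w`` (tiled across channels if joint)."""
        reps = self.w.shape[1] // self.patches.mask.shape[1]
        if reps == 1:
            return self.patches.mask
        return np.tile(self.patches.mask, (1, reps))
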