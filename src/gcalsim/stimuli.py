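"""Synthetic visual stimuli.

Two families cover everything the simulator consumes:

* training images — pairs of elongated (anisotropic) Gaussian blobs at uniform
  random positions and orientations, the canonical stimulus ensemble for
  developing orientation maps; and
* test images — sinusoidal luminance gratings parameterized by spatial
  frequency (cycles per image width of the cortical unit area), contrast
  (fraction of the [0, 1] luminance range), orientation and phase.

All images are luminance arrays in [0, 1] rendered on a sheet grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import MeasurementConfig, TrainingStimulusConfig
from .geometry import SheetGeometry

__all__ = [
    "GratingSpec",
    "oriented_gaussian_pair",
    "grating",
    "cs_battery",
    "map_battery",
    "test_battery",
    "save_png",
]


def save_png(image: np.ndarray, path) -> None:
    """Export a luminance image as 8-bit grayscale PNG."""
    import imageio.v3 as iio

    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    iio.imwrite(path, (arr * 255).round().astype(np.uint8))


@dataclass(frozen=True)
class GratingSpec:
    """A sinusoidal grating test stimulus.

    ``spatial_frequency`` is in cycles per unit sheet length (the V1 unit
    square), so 1.5 is the low- and 6 the medium-frequency test stimulus.
    ``orientation`` follows the stripe-orientation convention: pi/2 is a
    vertical grating (luminance varies along x only).
    """

    spatial_frequency: float
    contrast: float
    orientation: float = np.pi / 2
    phase: float = 0.0
    mean_luminance: float = 0.5

    def validate(self) -> "GratingSpec":
        if not 0.0 <= self.contrast <= 1.0:
            raise ValueError(f"contrast must lie in [0, 1], got {self.contrast}")
        if self.spatial_frequency < 0:
            raise ValueError("spatial_frequency must be >= 0")
        return self


def oriented_gaussian_pair(
    rng: np.random.Generator,
    spec: TrainingStimulusConfig,
    sheet: SheetGeometry,
) -> np.ndarray:
    """Render one training image: ``n_blobs`` oriented Gaussians, sum capped at peak.

    Blob centers are uniform over the sheet bounds and major-axis orientations
    uniform over [0, pi).  One call consumes exactly ``3 * n_blobs`` draws from
    ``rng``, so the stimulus stream is reproducible from the generator state.
    """
    x, y = sheet.grid()
    img = np.zeros(sheet.shape)
    s_minor = spec.sigma_minor
    s_major = spec.sigma_minor * spec.aspect_ratio
    bound = spec.position_bound if spec.position_bound is not None else sheet.radius
    for _ in range(spec.n_blobs):
        cx = rng.uniform(-bound, bound)
        cy = rng.uniform(-bound, bound)
        ori = rng.uniform(0.0, np.pi)
        dx = x - cx
        dy = y - cy
        # coordinates along (u) and across (v) the major axis
        u = dx * np.cos(ori) + dy * np.sin(ori)
        v = -dx * np.sin(ori) + dy * np.cos(ori)
        img += spec.peak * np.exp(-(u**2) / (2 * s_major**2) - (v**2) / (2 * s_minor**2))
    return np.minimum(img, spec.peak)


def grating(spec: GratingSpec, sheet: SheetGeometry) -> np.ndarray:
    """Render a sinusoidal grating on a sheet grid.

    ``I(x, y) = mean + (contrast / 2) * sin(2 pi f u + phase)`` where ``u`` is
    the coordinate perpendicular to the stripes, so the rendered range is
    ``mean -/+ contrast / 2`` up to discretization.
    """
    spec.validate()
    x, y = sheet.grid()
    u = x * np.sin(spec.orientation) - y * np.cos(spec.orientation)
    img = spec.mean_luminance + (spec.contrast / 2.0) * np.sin(
        2 * np.pi * spec.spatial_frequency * u + spec.phase
    )
    return np.clip(img, 0.0, 1.0)


def cs_battery(measurement: MeasurementConfig | None = None) -> list[GratingSpec]:
    """The contrast-sensitivity battery: vertical gratings, SF x contrast grid."""
    m = measurement or MeasurementConfig()
    orientations = [np.pi / 2]
    if m.include_oblique:
        orientations += [0.0, np.pi / 4]
    return [
        GratingSpec(spatial_frequency=f, contrast=c, orientation=o)
        for o in orientations
        for f in m.cs_frequencies
        for c in m.cs_contrasts
    ]


def map_battery(measurement: MeasurementConfig | None = None) -> list[GratingSpec]:
    """The orientation-map battery: orientations x phases at fixed contrast."""
    m = measurement or MeasurementConfig()
    oris = np.arange(m.map_orientations) * np.pi / m.map_orientations
    phases = np.arange(m.map_phases) * 2 * np.pi / m.map_phases
    return [
        GratingSpec(
            spatial_frequency=m.map_frequency,
            contrast=m.map_contrast,
            orientation=float(o),
            phase=float(p),
        )
        for o in oris
        for p in phases
    ]


def test_battery(measurement: MeasurementConfig | None = None) -> dict:
    """Both post-training batteries keyed by purpose."""
    return {"contrast_sensitivity": cs_battery(measurement), "orientation_map": map_battery(measurement)}
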