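"""Model configuration: every tunable scalar of the simulator, named and documented.

The configuration is a tree of frozen-by-convention dataclasses.  A resolved
``ModelConfig`` is attached to every model state; perturbation experiments act on
the state's *copy* of the config by dotted-path overrides (e.g.
``v1_lateral_inhibitory.strength``), never on weight arrays, so every
manipulation is a reversible scalar change.

Defaults follow the published GCAL parameterization of orientation-map
development: a retina photoreceptor sheet feeding difference-of-Gaussians LGN
On/Off channels with divisive contrast gain control, and a recurrently
connected V1 sheet with Hebbian afferent and lateral-inhibitory plasticity and
homeostatic threshold adaptation.
"""

from __future__ import annotations

import dataclasses
import difflib
from dataclasses import dataclass, field
from typing import Any

import yaml

__all__ = [
    "ConfigurationError",
    "SheetsConfig",
    "DoGProjectionConfig",
    "GainControlConfig",
    "AfferentConfig",
    "LateralConfig",
    "HomeostasisConfig",
    "TimeCourseConfig",
    "TrainingStimulusConfig",
    "MeasurementConfig",
    "ModelConfig",
    "default_config",
    "load_config",
    "apply_overrides",
    "config_to_dict",
    "config_from_dict",
]


class ConfigurationError(ValueError):
    """Raised for inconsistent, unknown or out-of-range configuration values."""


@dataclass
class SheetsConfig:
    """Sheet densities (units per unit sheet length) and the V1 extent.

    V1 spans a square of half-extent ``v1_radius``; the LGN and retina sheets are
    enlarged by the sum of the intervening connection-field radii so that no V1 or
    LGN unit has a truncated feedforward field.
    """

    retina_density: int = 24
    lgn_density: int = 24
    v1_density: int = 48
    v1_radius: float = 0.5


@dataclass
class DoGProjectionConfig:
    """Fixed retina -> LGN difference-of-Gaussians connection field.

    Center and surround lobes are each normalized to unit volume, so a uniform
    image produces zero net drive.  The Off channel is the sign-flipped On
    kernel.  ``strength`` is the channel gain applied to the linear drive.
    """

    sigma_center: float = 0.030
    sigma_surround: float = 0.120
    radius: float = 0.375
    strength: float = 2.33


@dataclass
class GainControlConfig:
    """Divisive contrast gain control within each LGN channel.

    Each unit's rectified drive is divided by ``saturation`` plus ``strength``
    times a wide-Gaussian pooling (``sigma``, truncated at ``radius``) of the
    channel's own rectified drive.  ``strength = 0`` disables gain control,
    recovering the rectified DoG response scaled by 1/``saturation``.
    """

    sigma: float = 0.15
    radius: float = 0.25
    strength: float = 5.0
    saturation: float = 0.11


@dataclass
class AfferentConfig:
    """Plastic LGN -> V1 connection fields (On and Off jointly normalized).

    Weights start as uniform random values under a Gaussian envelope
    (``envelope_sigma``) within a circular ``radius``, and are normalized to unit
    sum per V1 unit across both channels.  ``learning_rate`` is the Hebbian rate
    per iteration; the default 0.01 is the rate whose tripling (to 0.03) defines
    the elevated-plasticity manipulations.
    """

    radius: float = 0.27083
    envelope_sigma: float = 0.135415
    strength: float = 1.5
    learning_rate: float = 0.01


@dataclass
class LateralConfig:
    """One lateral projection within V1 (excitatory or inhibitory).

    Weights start as isotropic Gaussians (``sigma``) truncated at ``radius`` and
    normalized per unit.  The excitatory field is narrow and fixed by default
    (learning rate 0); the inhibitory field is wider and plastic.
    """

    sigma: float
    radius: float
    strength: float
    learning_rate: float


@dataclass
class HomeostasisConfig:
    """Per-unit adaptive threshold driving mean V1 activity toward a target.

    After each iteration the exponentially smoothed activity trace
    ``ybar <- (1 - smoothing) * eta + smoothing * ybar`` is updated and the
    threshold moves by ``adaptation_rate * (ybar - target_activity)``.
    """

    target_activity: float = 0.019
    adaptation_rate: float = 0.01
    smoothing: float = 0.991
    initial_threshold: float = 0.15


@dataclass
class TimeCourseConfig:
    """Discrete time-stepping of one stimulus presentation.

    One iteration spans unit model time in steps of ``dt`` (nominally ~12.5 ms
    each): image onset at t=0, LGN response at t+dt, first V1 (afferent-only)
    response at t+2*dt, then recurrent lateral settling from ``settle_start`` to
    ``settle_end`` inclusive.
    """

    dt: float = 0.05
    settle_start: float = 0.15
    settle_end: float = 0.95

    @property
    def settle_steps(self) -> int:
        return int(round((self.settle_end - self.settle_start) / self.dt)) + 1


@dataclass
class TrainingStimulusConfig:
    """Training images: pairs of elongated Gaussian blobs at random position/orientation.

    ``sigma_minor``/``aspect_ratio`` set blob geometry in sheet coordinates;
    positions are uniform over the retina bounds and orientations uniform over
    [0, pi).  Blob sum is capped at ``peak`` so images stay within [0, 1].
    """

    n_blobs: int = 2
    sigma_minor: float = 0.044194
    aspect_ratio: float = 4.66667
    peak: float = 1.0
    #: half-extent of the blob-center distribution; None means the full retina.
    #: The default covers the LGN-projecting region, so presentations land
    #: where they can drive the modeled cortex.
    position_bound: float | None = None


@dataclass
class MeasurementConfig:
    """Test batteries and orientation-map analysis settings.

    The contrast-sensitivity battery is vertical sinusoidal gratings at
    ``cs_frequencies`` cycles/image crossed with ``cs_contrasts`` (fractions of
    the [0, 1] input range).  The orientation-map battery sweeps
    ``map_orientations`` orientations x ``map_phases`` phases at
    ``map_contrast``, aggregated per unit by the maximum over phases.  Tuning
    histograms use ``n_bins`` bins over [0, pi) and weight each unit's
    preference by its activation to the ``histogram_frequency`` grating at
    ``histogram_contrast``.
    """

    cs_frequencies: tuple = (1.5, 6.0)
    cs_contrasts: tuple = (0.05, 0.10, 0.20, 0.40, 0.80)
    include_oblique: bool = False
    map_orientations: int = 8
    map_phases: int = 8
    map_contrast: float = 0.8
    map_frequency: float = 3.75
    n_bins: int = 36
    histogram_frequency: float = 6.0
    histogram_contrast: float = 0.8
    bimodality_trough_fraction: float = 0.8


@dataclass
class ModelConfig:
    """Complete resolved model configuration."""

    sheets: SheetsConfig = field(default_factory=SheetsConfig)
    retina_to_lgn: DoGProjectionConfig = field(default_factory=DoGProjectionConfig)
    lgn_gain_control: GainControlConfig = field(default_factory=GainControlConfig)
    lgn_to_v1: AfferentConfig = field(default_factory=AfferentConfig)
    v1_lateral_excitatory: LateralConfig = field(
        default_factory=lambda: LateralConfig(
            sigma=0.020, radius=0.104, strength=1.7, learning_rate=0.0
        )
    )
    v1_lateral_inhibitory: LateralConfig = field(
        default_factory=lambda: LateralConfig(
            sigma=0.075, radius=0.22917, strength=1.4, learning_rate=0.3
        )
    )
    homeostasis: HomeostasisConfig = field(default_factory=HomeostasisConfig)
    timecourse: TimeCourseConfig = field(default_factory=TimeCourseConfig)
    training_stimuli: TrainingStimulusConfig = field(default_factory=TrainingStimulusConfig)
    measurement: MeasurementConfig = field(default_factory=MeasurementConfig)
    #: "piecewise_linear" (half-rectification with saturation at 1) or "logistic".
    output_fn: str = "piecewise_linear"
    logistic_slope: float = 12.0

    # -- validation ---------------------------------------------------------

    def validate(self) -> "ModelConfig":
        s = self.sheets
        if s.retina_density <= 0 or s.lgn_density <= 0 or s.v1_density <= 0:
            raise ConfigurationError("sheet densities must be positive")
        if s.v1_density != 2 * s.lgn_density:
            raise ConfigurationError(
                "V1 must have 4x the units per visual area of the LGN sheets "
                f"(v1_density={s.v1_density}, lgn_density={s.lgn_density})"
            )
        if self.retina_to_lgn.sigma_surround <= self.retina_to_lgn.sigma_center:
            raise ConfigurationError("DoG surround sigma must exceed center sigma")
        if self.v1_lateral_inhibitory.radius <= self.v1_lateral_excitatory.radius:
            raise ConfigurationError(
                "lateral inhibitory radius must exceed lateral excitatory radius"
            )
        for name in ("lgn_to_v1", "v1_lateral_excitatory", "v1_lateral_inhibitory"):
            proj = getattr(self, name)
            if proj.radius <= 0:
                raise ConfigurationError(f"{name}.radius must be positive")
            if proj.strength < 0 or proj.learning_rate < 0:
                raise ConfigurationError(f"{name}: strength and learning_rate must be >= 0")
        h = self.homeostasis
        if not 0 < h.target_activity < 1:
            raise ConfigurationError("homeostasis.target_activity must lie in (0, 1)")
        if h.adaptation_rate < 0 or not 0 <= h.smoothing < 1:
            raise ConfigurationError("homeostasis rates out of range")
        if self.output_fn not in ("piecewise_linear", "logistic"):
            raise ConfigurationError(f"unknown output_fn {self.output_fn!r}")
        return self

    # -- sheet bounds -------------------------------------------------------

    @property
    def lgn_radius(self) -> float:
        """LGN half-extent: V1 extent plus the afferent connection radius."""
        d = self.sheets.lgn_density
        extra = _snap_up(self.lgn_to_v1.radius, d)
        return self.sheets.v1_radius + extra

    @property
    def retina_radius(self) -> float:
        """Retina half-extent: LGN extent plus the (grid-snapped) DoG radius.

        The snap matches the DoG kernel footprint so that valid-mode
        correlation of the retina maps exactly onto the LGN grid.
        """
        import math

        d = self.sheets.retina_density
        h = math.floor(self.retina_to_lgn.radius * d + 0.5 + 1e-9)
        return self.lgn_radius + h / d


def _snap_up(radius: float, density: int) -> float:
    """Round a radius up to a half-integer number of grid steps.

    Keeps sheet sizes integral while guaranteeing full connection fields.
    """
    import math

    return math.ceil(radius * density * 2 - 1e-9) / (2 * density)


def default_config() -> ModelConfig:
    return ModelConfig().validate()


# ---------------------------------------------------------------------------
# dict / YAML round-trips and dotted-path overrides
# ---------------------------------------------------------------------------


def config_to_dict(cfg: ModelConfig) -> dict:
    return dataclasses.asdict(cfg)


def _fill(template, data: dict, path: str):
    """Recursively overlay a nested dict onto a template dataclass instance."""
    names = {f.name for f in dataclasses.fields(type(template))}
    kwargs = {}
    for key, value in data.items():
        if key not in names:
            hint = difflib.get_close_matches(key, names, n=1)
            suggestion = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ConfigurationError(f"unknown config key {path}{key!r}{suggestion}")
        default_value = getattr(template, key)
        if dataclasses.is_dataclass(default_value) and isinstance(value, dict):
            kwargs[key] = _fill(default_value, value, f"{path}{key}.")
        elif isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return dataclasses.replace(template, **kwargs)


def config_from_dict(data: dict) -> ModelConfig:
    cfg = _fill(ModelConfig(), dict(data), "")
    return cfg.validate()


def valid_paths(cfg: ModelConfig | None = None, prefix: str = "") -> list[str]:
    """All dotted scalar paths of the configuration tree."""
    cfg = cfg or default_config()
    out: list[str] = []
    for f in dataclasses.fields(cfg):
        value = getattr(cfg, f.name)
        if dataclasses.is_dataclass(value):
            out.extend(valid_paths(value, prefix + f.name + "."))
        else:
            out.append(prefix + f.name)
    return out


def get_path(cfg: ModelConfig, path: str) -> Any:
    obj: Any = cfg
    for part in path.split("."):
        if not hasattr(obj, part):
            raise ConfigurationError(
                f"unknown config path {path!r}; valid paths include: "
                + ", ".join(valid_paths(cfg)[:])
            )
        obj = getattr(obj, part)
    return obj


def set_path(cfg: ModelConfig, path: str, value: Any) -> None:
    parts = path.split(".")
    obj: Any = cfg
    for part in parts[:-1]:
        if not hasattr(obj, part):
            raise ConfigurationError(
                f"unknown config path {path!r}; valid paths include: "
                + ", ".join(valid_paths(cfg))
            )
        obj = getattr(obj, part)
    if not hasattr(obj, parts[-1]):
        near = difflib.get_close_matches(parts[-1], [p.split(".")[-1] for p in valid_paths(cfg)], n=1)
        suggestion = f"; did you mean {near[0]!r}?" if near else ""
        raise ConfigurationError(f"unknown config path {path!r}{suggestion}")
    setattr(obj, parts[-1], value)


def apply_overrides(cfg: ModelConfig, overrides: dict[str, Any]) -> ModelConfig:
    """Apply ``{"dotted.path": value}`` overrides in place and re-validate."""
    for path, value in (overrides or {}).items():
        current = get_path(cfg, path)
        if dataclasses.is_dataclass(current):
            raise ConfigurationError(f"config path {path!r} is a section, not a scalar")
        set_path(cfg, path, value)
    return cfg.validate()


def load_config(path: str | None = None, overrides: dict[str, Any] | None = None) -> ModelConfig:
    """Load a YAML config file (or the defaults) and apply dotted-path overrides.

    Unknown keys are rejected with the nearest valid key named; a malformed
    file raises a parse error carrying the line number (from the YAML parser).
    """
    if path is None:
        cfg = default_config()
    else:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file {path} must contain a mapping")
        cfg = config_from_dict(data)
    return apply_overrides(cfg, overrides or {})
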