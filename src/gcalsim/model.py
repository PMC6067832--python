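"""The feedforward/lateral machinery: sheets, kernels, LGN gain control, V1 settling.

The simulator is a four-sheet firing-rate network.  A luminance image drives
the retina; fixed difference-of-Gaussians (DoG) connection fields produce
linear On/Off drive at the LGN sheets, which is half-rectified and divisively
normalized by pooled neighboring activity (contrast gain control).  V1 units
receive plastic afferent fields from both LGN channels and settle recurrently
through narrow excitatory and wide inhibitory lateral fields, with a per-unit
adaptive threshold inside a piecewise-linear (or optionally logistic) output
nonlinearity bounded in [0, 1].
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from . import _kernels
from .config import ConfigurationError, ModelConfig, default_config
from .geometry import SheetGeometry
from .projections import (
    Projection,
    build_patches,
    gaussian_weights,
    random_envelope_weights,
)

__all__ = [
    "DoGParams",
    "ModelState",
    "SettlingError",
    "build_model",
    "dog_kernel",
    "dog_response",
    "lgn_step",
    "v1_settle",
]


class _FFTCorrelator:
    """Correlation with a fixed kernel via a precomputed kernel FFT.

    ``mode`` is 'valid' (feedforward DoG: enlarged retina maps exactly onto
    the LGN grid) or 'same' (lateral pooling with zero padding, renormalized
    by the caller at the edges).
    """

    def __init__(self, kernel: np.ndarray, in_shape: tuple, mode: str = "valid"):
        from scipy import fft as _fft

        kh, kw = kernel.shape
        self.kernel = kernel
        self.full_shape = (in_shape[0] + kh - 1, in_shape[1] + kw - 1)
        self.fshape = (
            _fft.next_fast_len(self.full_shape[0]),
            _fft.next_fast_len(self.full_shape[1]),
        )
        # correlation = convolution with the flipped kernel
        self.kf = _fft.rfft2(kernel[::-1, ::-1], self.fshape)
        if mode == "valid":
            r0, c0 = kh - 1, kw - 1
            out_shape = (in_shape[0] - kh + 1, in_shape[1] - kw + 1)
        elif mode == "same":
            r0, c0 = (kh - 1) // 2 + (kh % 2 == 0), (kw - 1) // 2 + (kw % 2 == 0)
            out_shape = in_shape
        else:  # pragma: no cover
            raise ValueError(mode)
        self.rows = slice(r0, r0 + out_shape[0])
        self.cols = slice(c0, c0 + out_shape[1])

    def __call__(self, image: np.ndarray) -> np.ndarray:
        from scipy import fft as _fft

        full = _fft.irfft2(_fft.rfft2(image, self.fshape) * self.kf, self.fshape)
        return full[self.rows, self.cols]


class SettlingError(RuntimeError):
    """Non-finite activity encountered during recurrent settling."""

    def __init__(self, step: int):
        self.step = step
        super().__init__(f"non-finite V1 activity at settle step {step}")


@dataclass(frozen=True)
class DoGParams:
    """Difference-of-Gaussians receptive field (center-surround)."""

    sigma_center: float
    sigma_surround: float
    polarity: str = "on_center"  # or "off_center"

    def __post_init__(self):
        if self.sigma_surround <= self.sigma_center:
            raise ValueError("sigma_surround must exceed sigma_center")
        if self.polarity not in ("on_center", "off_center"):
            raise ValueError(f"unknown polarity {self.polarity!r}")


def dog_kernel(params: DoGParams, radius: float, density: int) -> np.ndarray:
    """DoG kernel on the source grid, center and surround each of unit volume.

    Unit volume per lobe makes the kernel zero-sum, so uniform input yields
    zero drive.
    """
    h = int(math.floor(radius * density + 0.5 + 1e-9))
    c = np.arange(-h, h + 1) / density
    x, y = np.meshgrid(c, c)
    d2 = x**2 + y**2
    mask = d2 <= radius**2 + 1e-12
    center = np.exp(-d2 / (2 * params.sigma_center**2)) * mask
    surround = np.exp(-d2 / (2 * params.sigma_surround**2)) * mask
    center /= center.sum()
    surround /= surround.sum()
    kern = center - surround
    return kern if params.polarity == "on_center" else -kern


def dog_response(image: np.ndarray, params: DoGParams, radius: float, density: int) -> np.ndarray:
    """Linear center-surround drive of an LGN-density sheet to a retinal image.

    Valid-mode correlation: the output sheet is smaller than the retina by the
    kernel footprint, which is exactly the enlarged-retina construction used by
    the model, so every output unit has a full field.
    """
    image = np.asarray(image, dtype=float)
    if image.min() < -1e-9 or image.max() > 1.0 + 1e-9:
        raise ValueError("image luminance must lie in [0, 1]")
    kern = dog_kernel(params, radius, density)
    return signal.correlate(image, kern, mode="valid", method="direct")


# ---------------------------------------------------------------------------
# Model state
# ---------------------------------------------------------------------------


@dataclass
class ModelState:
    """Full simulator state.

    Everything needed to continue or reproduce a run: resolved config, sheet
    geometries, fixed kernels, plastic projection weights, per-V1-unit adaptive
    thresholds and smoothed activity traces, the iteration counter and the RNG.
    """

    config: ModelConfig
    seed: int
    sheets: dict
    dog: np.ndarray  # fixed retina->LGN On kernel (Off is its negative)
    dog_corr: "_FFTCorrelator"
    pool_kernel: np.ndarray  # gain-control pooling kernel (unit sum)
    pool_corr: "_FFTCorrelator"
    pool_norm: np.ndarray  # per-unit normalization of the truncated pool
    afferent: Projection  # LGN (On+Off) -> V1, jointly normalized
    lateral_exc: Projection
    lateral_inh: Projection
    theta: np.ndarray  # (n_v1,) adaptive thresholds
    ybar: np.ndarray  # (n_v1,) smoothed activity trace
    iteration: int
    rng: np.random.Generator
    log: list = field(default_factory=list)
    perturbation_log: list = field(default_factory=list)

    # -- convenience --------------------------------------------------------

    @property
    def v1_shape(self) -> tuple:
        return self.sheets["v1"].shape

    def copy(self) -> "ModelState":
        """Independent copy of all mutable content.

        Weights, thresholds, traces, config, logs and the RNG stream are
        copied; immutable structure (sheet geometry, patch indices/masks,
        fixed kernels) is shared.
        """
        from dataclasses import replace as _replace

        def clone(proj):
            return _replace(proj, w=proj.w.copy())

        new = ModelState(
            config=copy.deepcopy(self.config),
            seed=self.seed,
            sheets=self.sheets,
            dog=self.dog,
            dog_corr=self.dog_corr,
            pool_kernel=self.pool_kernel,
            pool_corr=self.pool_corr,
            pool_norm=self.pool_norm,
            afferent=clone(self.afferent),
            lateral_exc=clone(self.lateral_exc),
            lateral_inh=clone(self.lateral_inh),
            theta=self.theta.copy(),
            ybar=self.ybar.copy(),
            iteration=self.iteration,
            rng=copy.deepcopy(self.rng),
            log=copy.deepcopy(self.log),
            perturbation_log=copy.deepcopy(self.perturbation_log),
        )
        return new

    def projections(self) -> dict:
        return {
            "lgn_to_v1": self.afferent,
            "v1_lateral_excitatory": self.lateral_exc,
            "v1_lateral_inhibitory": self.lateral_inh,
        }

    def content_hash(self) -> str:
        """Hash of all mutable numerical content (for no-side-effect checks)."""
        import hashlib

        h = hashlib.sha256()
        for arr in (
            self.afferent.w,
            self.lateral_exc.w,
            self.lateral_inh.w,
            self.theta,
            self.ybar,
        ):
            h.update(np.ascontiguousarray(arr).tobytes())
        h.update(str(self.iteration).encode())
        h.update(repr(self.rng.bit_generator.state).encode())
        h.update(repr(self.config).encode())
        return h.hexdigest()


def _pool_kernel_1d(sigma: float, radius: float, density: int) -> np.ndarray:
    h = int(math.floor(radius * density + 0.5 + 1e-9))
    c = np.arange(-h, h + 1) / density
    k = np.exp(-(c**2) / (2 * sigma**2))
    return k / k.sum()


def build_model(config: ModelConfig | None = None, seed: int = 0) -> ModelState:
    """Assemble a model in its naive (untrained) condition.

    Identical ``(config, seed)`` pairs yield bitwise-identical states.  The
    retina and LGN sheets are sized so every connection field fits fully inside
    its source sheet; a radius that cannot fit raises a configuration error
    naming the projection.
    """
    cfg = copy.deepcopy(config) if config is not None else default_config()
    cfg.validate()
    s = cfg.sheets
    # connection fields wider than the whole modeled area cannot fit inside a
    # sanely-sized source sheet; name the offending projection
    area = 2.0 * s.v1_radius
    for pname, radius in (
        ("retina_to_lgn", cfg.retina_to_lgn.radius),
        ("lgn_to_v1", cfg.lgn_to_v1.radius),
        ("v1_lateral_excitatory", cfg.v1_lateral_excitatory.radius),
        ("v1_lateral_inhibitory", cfg.v1_lateral_inhibitory.radius),
    ):
        if radius > area:
            raise ConfigurationError(
                f"projection {pname!r}: connection-field radius {radius} exceeds "
                f"the modeled area (width {area}); fields cannot fit inside the "
                "source sheet"
            )
    v1 = SheetGeometry("v1", s.v1_density, s.v1_radius)
    lgn_on = SheetGeometry("lgn_on", s.lgn_density, cfg.lgn_radius)
    lgn_off = SheetGeometry("lgn_off", s.lgn_density, cfg.lgn_radius)
    retina = SheetGeometry("retina", s.retina_density, cfg.retina_radius)
    sheets = {"retina": retina, "lgn_on": lgn_on, "lgn_off": lgn_off, "v1": v1}

    # retina -> LGN: the sheets share a density, so the valid correlation of the
    # retina image with the DoG kernel must land exactly on the LGN grid.
    if s.retina_density != s.lgn_density:
        raise ConfigurationError("retina and LGN densities must match")
    kern = dog_kernel(
        DoGParams(cfg.retina_to_lgn.sigma_center, cfg.retina_to_lgn.sigma_surround),
        cfg.retina_to_lgn.radius,
        s.retina_density,
    )
    expected = retina.n - (kern.shape[0] - 1)
    if expected != lgn_on.n:
        raise ConfigurationError(
            f"projection 'retina_to_lgn': kernel radius {cfg.retina_to_lgn.radius} does "
            f"not tile the retina ({retina.n}) onto the LGN ({lgn_on.n})"
        )

    pool1d = _pool_kernel_1d(
        cfg.lgn_gain_control.sigma, cfg.lgn_gain_control.radius, s.lgn_density
    )
    pool_kernel = np.outer(pool1d, pool1d)
    pool_corr = _FFTCorrelator(pool_kernel, lgn_on.shape, mode="same")
    pool_norm = pool_corr(np.ones(lgn_on.shape))
    dog_corr = _FFTCorrelator(kern, retina.shape, mode="valid")

    rng = np.random.default_rng(seed)

    aff_patches = build_patches(lgn_on, v1, cfg.lgn_to_v1.radius, "lgn_to_v1", require_full_fit=True)
    w_on = random_envelope_weights(aff_patches, cfg.lgn_to_v1.envelope_sigma, rng)
    w_off = random_envelope_weights(aff_patches, cfg.lgn_to_v1.envelope_sigma, rng)
    w_aff = np.concatenate([w_on, w_off], axis=1)
    w_aff /= w_aff.sum(axis=1, keepdims=True)
    afferent = Projection("lgn_to_v1", ("lgn_on", "lgn_off"), aff_patches, w_aff, plastic=True)

    exc_patches = build_patches(v1, v1, cfg.v1_lateral_excitatory.radius, "v1_lateral_excitatory")
    lateral_exc = Projection(
        "v1_lateral_excitatory",
        ("v1",),
        exc_patches,
        gaussian_weights(exc_patches, cfg.v1_lateral_excitatory.sigma),
        plastic=True,
    )
    inh_patches = build_patches(v1, v1, cfg.v1_lateral_inhibitory.radius, "v1_lateral_inhibitory")
    lateral_inh = Projection(
        "v1_lateral_inhibitory",
        ("v1",),
        inh_patches,
        gaussian_weights(inh_patches, cfg.v1_lateral_inhibitory.sigma),
        plastic=True,
    )

    # free the build-time distance arrays (weights are already constructed)
    for proj in (afferent, lateral_exc, lateral_inh):
        proj.patches.dist2 = None

    n_v1 = v1.n_units
    return ModelState(
        config=cfg,
        seed=seed,
        sheets=sheets,
        dog=kern,
        dog_corr=dog_corr,
        pool_kernel=pool_kernel,
        pool_corr=pool_corr,
        pool_norm=pool_norm,
        afferent=afferent,
        lateral_exc=lateral_exc,
        lateral_inh=lateral_inh,
        theta=np.full(n_v1, cfg.homeostasis.initial_threshold),
        ybar=np.full(n_v1, cfg.homeostasis.target_activity),
        iteration=0,
        rng=rng,
    )


# ---------------------------------------------------------------------------
# Per-presentation dynamics
# ---------------------------------------------------------------------------


def _pool(state: ModelState, a: np.ndarray) -> np.ndarray:
    """Edge-renormalized Gaussian pooling over an LGN sheet."""
    return state.pool_corr(a) / state.pool_norm


def lgn_step(state: ModelState, image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """On/Off channel responses with divisive contrast gain control.

    Each channel half-rectifies its (gain-scaled) DoG drive and divides by a
    saturation constant plus the gain-control strength times a wide Gaussian
    pooling of the channel's own rectified drive; outputs are clipped to [0, 1].
    With gain-control strength 0 this reduces to the rectified DoG response
    divided by the saturation constant.
    """
    image = np.asarray(image, dtype=float)
    if image.shape != state.sheets["retina"].shape:
        raise ValueError(
            f"image shape {image.shape} != retina shape {state.sheets['retina'].shape}"
        )
    if image.min() < -1e-9 or image.max() > 1.0 + 1e-9:
        raise ValueError("image luminance must lie in [0, 1]")
    drive = state.dog_corr(image)
    gamma_l = state.config.retina_to_lgn.strength
    gc = state.config.lgn_gain_control
    out = []
    for channel_drive in (drive, -drive):
        a = np.maximum(gamma_l * channel_drive, 0.0)
        if gc.strength > 0:
            denom = gc.saturation + gc.strength * _pool(state, a)
        else:
            denom = gc.saturation
        out.append(np.clip(a / denom, 0.0, 1.0))
    return out[0], out[1]


def afferent_drive(state: ModelState, on: np.ndarray, off: np.ndarray) -> np.ndarray:
    """Afferent input to each V1 unit: gain times the joint weighted LGN sum."""
    return state.config.lgn_to_v1.strength * state.afferent.activate(
        on.ravel(), off.ravel()
    )


def v1_settle(
    state: ModelState,
    on: np.ndarray,
    off: np.ndarray,
    record: bool = False,
):
    """Settle V1 recurrently for the configured number of lateral steps.

    The afferent drive is computed once and held constant; the first V1
    response is afferent-only, after which the configured number of recurrent
    steps (default 17, the 0.15..0.95 settling window in steps of 0.05) apply
    the lateral excitatory and inhibitory fields.  Weights and thresholds are
    not modified.  With ``record=True`` the per-step activity trace is returned
    alongside the settled activity.
    """
    cfg = state.config
    aff = afferent_drive(state, on, off)
    if not (np.all(np.isfinite(aff)) and np.all(np.isfinite(state.theta))):
        raise SettlingError(0)
    n_steps = cfg.timecourse.settle_steps
    mode = 0 if cfg.output_fn == "piecewise_linear" else 1
    gE = cfg.v1_lateral_excitatory.strength
    gI = cfg.v1_lateral_inhibitory.strength
    if record:
        act, bad = _settle_recorded(state, aff, gE, gI, n_steps, mode)
    else:
        exc, inh = state.lateral_exc, state.lateral_inh
        n_side = state.sheets["v1"].n
        if _kernels.HAVE_NUMBA:
            act, bad = _kernels.settle(
                aff,
                exc.w,
                _patch_half_width(exc),
                inh.w,
                _patch_half_width(inh),
                state.theta,
                n_side,
                gE,
                gI,
                n_steps,
                mode,
                cfg.logistic_slope,
            )
        else:  # pragma: no cover - exercised only without numba
            act, bad = _kernels._settle_np(
                aff,
                exc.w,
                exc.patches.idx,
                _patch_half_width(exc),
                inh.w,
                inh.patches.idx,
                _patch_half_width(inh),
                state.theta,
                n_side,
                gE,
                gI,
                n_steps,
                mode,
                cfg.logistic_slope,
            )
    if bad == -1 and not record and not np.all(np.isfinite(act)):
        # the fast path runs with fastmath; locate the failing step precisely
        _, bad = _settle_recorded(state, aff, gE, gI, n_steps, mode)
        if bad == -1:
            bad = 0
    if bad != -1:
        raise SettlingError(bad)
    if record:
        return act[-1].reshape(state.v1_shape), [a.reshape(state.v1_shape) for a in act]
    return act.reshape(state.v1_shape)


def _patch_half_width(proj) -> int:
    width = int(round(proj.patches.idx.shape[1] ** 0.5))
    return (width - 1) // 2


def _settle_recorded(state, aff, gE, gI, n_steps, mode):
    """Numpy settling that keeps the full step-by-step trace."""
    slope = state.config.logistic_slope

    def f(x):
        if mode == 0:
            return np.clip(x - state.theta, 0.0, 1.0)
        return 1.0 / (1.0 + np.exp(-slope * (x - state.theta - 0.5)))

    act = f(aff)
    trace = [act]
    idxE, wE = state.lateral_exc.patches.idx, state.lateral_exc.w
    idxI, wI = state.lateral_inh.patches.idx, state.lateral_inh.w
    for step in range(n_steps):
        exc = np.einsum("np,np->n", wE, act[idxE])
        inh = np.einsum("np,np->n", wI, act[idxI])
        act = f(aff + gE * exc - gI * inh)
        if not np.all(np.isfinite(act)):
            return trace, step + 1
        trace.append(act)
    return trace, -1


def present(state: ModelState, image: np.ndarray) -> np.ndarray:
    """One full read-out presentation (LGN step + V1 settling), no learning."""
    on, off = lgn_step(state, image)
    return v1_settle(state, on, off)
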