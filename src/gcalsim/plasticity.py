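"""Hebbian learning with divisive normalization, homeostasis, and the training loop.

After each stimulus presentation every plastic projection is updated as
``w <- w + alpha * pre * post`` followed by division of each target unit's
weight vector by its sum (jointly across the On and Off channels for the
afferent projection), so per-unit weight sums stay exactly 1.  A slow per-unit
threshold adaptation then moves each V1 unit's operating point toward the
target mean activity.  Learning uses the final settled V1 activity once per
iteration.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import _kernels
from .model import ModelState, SettlingError, lgn_step, v1_settle
from .stimuli import oriented_gaussian_pair

__all__ = ["DegenerateUnitWarning", "hebbian_update", "homeostatic_update", "train"]

#: Configured learning rates are expressed in per-connection-field units: the
#: per-connection Hebbian step is ``alpha * LEARNING_RATE_UNIT / field_size``.
#: The unit constant sets how much of a field's weight mass one iteration can
#: move at the baseline rates, and is part of the model's fixed
#: parameterization (rate *ratios*, e.g. a tripled afferent rate, are
#: unaffected by it).
LEARNING_RATE_UNIT = 10.0


class DegenerateUnitWarning(RuntimeWarning):
    """A unit's weights would have normalized over a zero sum; kept unchanged."""


def hebbian_update(
    w: np.ndarray,
    mask: np.ndarray,
    pre: np.ndarray,
    post: np.ndarray,
    alpha: float,
) -> int:
    """In-place Hebbian step with sum-to-one normalization.

    ``w`` and ``pre`` are (n_units, n_connections); ``post`` is (n_units,).
    ``alpha = 0`` and all-zero postsynaptic activity are exact no-ops (weights
    bitwise unchanged).  Units whose updated weights would sum to zero keep
    their previous weights and trigger a :class:`DegenerateUnitWarning`.
    Returns the number of such degenerate units.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if alpha == 0.0 or not np.any(post):
        return 0
    degenerate = _kernels.hebb(w, mask, pre, np.asarray(post, dtype=float), alpha)
    if degenerate:
        warnings.warn(
            f"{degenerate} unit(s) had zero weight sum at normalization; weights kept",
            DegenerateUnitWarning,
            stacklevel=2,
        )
    return degenerate


def homeostatic_update(state: ModelState, v1_activity: np.ndarray) -> None:
    """Update smoothed activity traces and adaptive thresholds in place.

    ``ybar <- (1 - beta) * eta + beta * ybar`` then
    ``theta <- theta + lambda * (ybar - mu)``; ``lambda = 0`` freezes thresholds.
    """
    h = state.config.homeostasis
    eta = np.asarray(v1_activity, dtype=float).ravel()
    state.ybar *= h.smoothing
    state.ybar += (1.0 - h.smoothing) * eta
    if h.adaptation_rate != 0.0:
        state.theta += h.adaptation_rate * (state.ybar - h.target_activity)


def train_step(state: ModelState, image: np.ndarray) -> np.ndarray:
    """One training iteration on a given image; returns the settled V1 activity."""
    cfg = state.config
    on, off = lgn_step(state, image)
    v1 = v1_settle(state, on, off)
    post = v1.ravel()

    updates = (
        (state.afferent, cfg.lgn_to_v1.learning_rate, (on.ravel(), off.ravel())),
        (state.lateral_exc, cfg.v1_lateral_excitatory.learning_rate, (post,)),
        (state.lateral_inh, cfg.v1_lateral_inhibitory.learning_rate, (post,)),
    )
    for proj, alpha, srcs in updates:
        if alpha > 0 and np.any(post):
            # configured rates are per connection field; the per-connection
            # step divides by the field size so rates are comparable across
            # projections with different field sizes
            degenerate = _kernels.hebb_gather(
                proj.w,
                proj.patches.mask,
                proj.patches.idx,
                list(srcs),
                post,
                alpha * LEARNING_RATE_UNIT / proj.w.shape[1],
            )
            if degenerate:
                warnings.warn(
                    f"{degenerate} unit(s) in {proj.name} had zero weight sum; kept",
                    DegenerateUnitWarning,
                    stacklevel=2,
                )

    homeostatic_update(state, post)
    state.iteration += 1
    return v1


def train(
    state: ModelState,
    n_iterations: int,
    stimulus_stream=None,
    log_every: int = 100,
) -> ModelState:
    """Run the self-organization loop for ``n_iterations`` in place.

    Each iteration draws a stimulus (from ``stimulus_stream`` if given,
    otherwise an oriented-Gaussian pair from the state's own RNG), runs the
    LGN step and V1 settling, applies Hebbian updates to every plastic
    projection with a nonzero learning rate, and updates homeostasis.  Fully
    reproducible given the state (including its RNG) at entry.
    """
    if n_iterations < 0:
        raise ValueError("n_iterations must be >= 0")
    retina = state.sheets["retina"]
    for i in range(n_iterations):
        if stimulus_stream is not None:
            image = next(stimulus_stream)
        else:
            image = oriented_gaussian_pair(state.rng, state.config.training_stimuli, retina)
        try:
            v1 = train_step(state, image)
        except SettlingError as exc:
            exc.iteration = state.iteration
            exc.args = (f"{exc.args[0]} (training iteration {state.iteration})",)
            raise
        if log_every and (state.iteration % log_every == 0 or i == n_iterations - 1):
            prev = getattr(state, "_w_snapshot", None)
            daff = float(np.abs(state.afferent.w - prev[0]).mean()) if prev else float("nan")
            dinh = float(np.abs(state.lateral_inh.w - prev[1]).mean()) if prev else float("nan")
            state._w_snapshot = (state.afferent.w.copy(), state.lateral_inh.w.copy())
            state.log.append(
                {
                    "iteration": state.iteration,
                    "mean_v1_activity": float(v1.mean()),
                    "mean_threshold": float(state.theta.mean()),
                    "mean_activity_trace": float(state.ybar.mean()),
                    "mean_afferent_weight_change": daff,
                    "mean_inhibitory_weight_change": dinh,
                }
            )
    return state
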